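"""Simulation orchestration.

``simulate`` runs the full pipeline: discretize the sequence on its
critical time nodes, partition the nodes into excitation/precession
blocks, split the spins into independent chunks, dispatch the regime
kernels per chunk, superpose the chunk signals, and package the result
as :class:`~blochsim.core.RawData` with the k-space trajectory attached.

Because every isochromat evolves independently, the acquired signal is
the plain sum of Mxy over spins (a single uniform receive coil, no
noise), and the result is invariant to the number of spin chunks and to
the number of simulation blocks.

Alternative spin-state representations (e.g. extended phase graphs) can
be plugged in by registering a :class:`SimulationMethod` whose hooks
replace the default Bloch kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    DiscreteSequence,
    GAMMA,
    Mag,
    Phantom,
    RawData,
    Readout,
    Scanner,
    Sequence,
    SimConfig,
    equilibrium_mag,
)
from .discretize import discretize, partition
from .kernels import excitation_step, precession_block

__all__ = [
    "SimulationMethod",
    "register_method",
    "get_method",
    "simulate",
    "signal_to_readouts",
    "k_trajectory",
]


def _bloch_initialize(phantom: Phantom) -> Mag:
    return equilibrium_mag(phantom)


def _bloch_excitation(
    state: Mag, phantom: Phantom, dsub: DiscreteSequence, gamma: float
):
    """Per-step spinor rotation + relaxation over an excitation span.

    The RF sample at the left node is used (the envelope is
    piecewise-constant on its raster, so this is its exact value over the
    step); the gradient enters as the step average, which matches the
    trapezoidal phase integral exactly when B1 = 0.
    """
    t = dsub.t
    samples = []
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        G = (
            0.5 * (dsub.Gx[i] + dsub.Gx[i + 1]),
            0.5 * (dsub.Gy[i] + dsub.Gy[i + 1]),
            0.5 * (dsub.Gz[i] + dsub.Gz[i + 1]),
        )
        state = excitation_step(
            state, phantom, dsub.B1[i], G, dt, 0.5 * (t[i] + t[i + 1]), gamma
        )
        if dsub.adc[i + 1]:
            samples.append(state.xy.sum())
    return state, np.asarray(samples, dtype=complex)


def _bloch_precession(
    state: Mag, phantom: Phantom, dsub: DiscreteSequence, gamma: float
):
    return precession_block(state, phantom, dsub, gamma)


@dataclass
class SimulationMethod:
    """Pluggable spin-state representation and regime handlers."""

    tag: str
    initialize_state: Callable
    run_excitation: Callable
    run_precession: Callable


_METHODS: dict = {}


def register_method(method: SimulationMethod) -> None:
    _METHODS[method.tag] = method


def get_method(tag: str) -> SimulationMethod:
    try:
        return _METHODS[tag]
    except KeyError:
        raise KeyError(
            f"unknown simulation method {tag!r}; registered: {sorted(_METHODS)}"
        ) from None


register_method(
    SimulationMethod(
        "bloch", _bloch_initialize, _bloch_excitation, _bloch_precession
    )
)


def simulate(
    phantom: Phantom,
    seq: Sequence,
    scanner: Scanner | None = None,
    config: SimConfig | None = None,
) -> RawData:
    """Simulate an acquisition and return the raw data.

    The spins are split into ``config.n_threads`` disjoint chunks whose
    partial signals are accumulated in separate buffers and summed — the
    same contract a parallel implementation must satisfy, so the output
    is bitwise-independent of the chunk count up to float summation
    order.
    """
    scanner = scanner or Scanner()
    config = config or SimConfig()
    gamma = scanner.gamma
    dseq = discretize(seq, config, scanner)
    blocks = partition(dseq, config)
    method = get_method(config.method)

    adc_nodes = np.nonzero(dseq.adc)[0]
    n_samples = len(adc_nodes)
    if n_samples == 0:
        warnings.warn("sequence has no ADC events; raw data will be empty")

    chunk_ids = np.array_split(np.arange(phantom.n_spins), config.n_threads)
    signal = np.zeros(n_samples, dtype=complex)
    for ids in chunk_ids:
        if len(ids) == 0:
            continue
        sub = phantom.subset(ids)
        state = method.initialize_state(sub)
        parts = []
        if n_samples and dseq.adc[0]:
            parts.append(np.asarray([state.xy.sum()], dtype=complex))
        for blk in blocks:
            dsub = dseq.node_slice(blk.start, blk.stop)
            if blk.regime == "excitation":
                state, s = method.run_excitation(state, sub, dsub, gamma)
            else:
                state, s = method.run_precession(state, sub, dsub, gamma)
            if len(s):
                parts.append(s)
        chunk_sig = (
            np.concatenate(parts) if parts else np.zeros(0, dtype=complex)
        )
        if len(chunk_sig) != n_samples:
            raise RuntimeError("internal error: sample count mismatch")
        signal += chunk_sig
    return signal_to_readouts(dseq, seq, signal, scanner, config)


def signal_to_readouts(
    dseq: DiscreteSequence,
    seq: Sequence,
    samples: np.ndarray,
    scanner: Scanner | None = None,
    config: SimConfig | None = None,
) -> RawData:
    """Group the per-node signal into one readout per ADC event.

    The ADC demodulation phase is applied as ``exp(-i*phase)`` and the
    k-space trajectory (if computable) is attached per readout.
    """
    scanner = scanner or Scanner()
    adc_nodes = np.nonzero(dseq.adc)[0]
    if len(samples) != len(adc_nodes):
        raise RuntimeError("samples not aligned with adc nodes")
    pos_of_node = {int(n): i for i, n in enumerate(adc_nodes)}
    trajs = k_trajectory(seq, scanner.gamma)
    readouts = []
    for (i_ev, (_, _, ev)), nodes in zip(
        enumerate(seq.adc_events()), dseq.adc_node_groups
    ):
        idx = np.asarray([pos_of_node[int(n)] for n in nodes])
        data = samples[idx] * np.exp(-1j * ev.phase)
        readouts.append(Readout(dseq.t[nodes].copy(), data, trajs[i_ev]))
    header = dict(seq.definitions)
    header.setdefault("sequence_name", seq.definitions.get("name", "sequence"))
    if config is not None:
        header["sim_params"] = config.snapshot()
    return RawData(readouts, header)


class _AxisIntegral:
    """Exact running integral of one gradient axis over the sequence."""

    def __init__(self, seq: Sequence, axis: str):
        starts = seq.block_starts
        events = []
        for i, b in enumerate(seq.blocks):
            for g in b.gradients():
                if g.axis == axis:
                    vt = starts[i] + g.times
                    areas = np.concatenate(
                        [
                            [0.0],
                            np.cumsum(
                                np.diff(vt)
                                * 0.5
                                * (g.amplitudes[:-1] + g.amplitudes[1:])
                            ),
                        ]
                    )
                    events.append((vt, g.amplitudes, areas))
        events.sort(key=lambda e: e[0][0])
        self.events = events

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for vt, amp, areas in self.events:
            after = t >= vt[-1]
            out[after] += areas[-1]
            inside = (t > vt[0]) & (t < vt[-1])
            if np.any(inside):
                ti = t[inside]
                idx = np.clip(np.searchsorted(vt, ti, side="right") - 1, 0, len(vt) - 2)
                a_t = amp[idx] + (amp[idx + 1] - amp[idx]) * (
                    (ti - vt[idx]) / (vt[idx + 1] - vt[idx])
                )
                out[inside] += areas[idx] + 0.5 * (amp[idx] + a_t) * (ti - vt[idx])
        return out


def k_trajectory(seq: Sequence, gamma: float = GAMMA) -> list:
    """k-space position (1/m) at every ADC sample, per readout.

    ``k(t) = (gamma/2pi) * int_0^t G dtau`` integrated exactly over the
    piecewise-linear gradients.  Excitation pulses do not reset k, but
    refocusing pulses listed in ``seq.definitions['refocus_times']``
    negate the accumulated k (the standard spin-echo bookkeeping).
    """
    c = gamma / (2.0 * np.pi)
    integrals = [_AxisIntegral(seq, ax) for ax in "xyz"]
    refocus = sorted(seq.definitions.get("refocus_times", []))

    def k_at(times: np.ndarray) -> np.ndarray:
        ks = np.zeros((len(times), 3))
        for j, integ in enumerate(integrals):
            I_t = integ(times)
            k_off = 0.0
            I_prev = 0.0
            raw = c * I_t  # no refocusing: k = c*I
            vals = raw.copy()
            for tr in refocus:
                k_tr = k_off + c * (integ(np.asarray([tr]))[0] - I_prev)
                later = times > tr
                k_off = -k_tr
                I_prev = integ(np.asarray([tr]))[0]
                vals[later] = k_off + c * (I_t[later] - I_prev)
            ks[:, j] = vals
        return ks

    out = []
    for _, t0, ev in seq.adc_events():
        out.append(k_at(t0 + ev.sample_times))
    return out
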