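"""Sequence-aware time stepping.

A :class:`~blochsim.core.Sequence` is turned into a
:class:`~blochsim.core.DiscreteSequence` whose nodes are exactly the
points the solver needs: block boundaries, gradient vertices (the
trapezoidal rule is exact between them for piecewise-linear gradients),
RF raster points, ADC sample times, and — when spins move — intermediate
nodes capped at ``dt``.  The nodes are then partitioned into simulation
blocks, each tagged excitation (contains nonzero RF) or precession.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    TIME_MERGE_TOL,
    DiscreteSequence,
    Scanner,
    SeqBlock,
    Sequence,
    SimConfig,
)

__all__ = ["SimBlock", "critical_times", "discretize", "partition"]


@dataclass
class SimBlock:
    """Contiguous node span [start, stop] (inclusive) with a regime tag.

    The block owns the steps ``start .. stop-1``; consecutive blocks share
    their boundary node, so the spin state flows through unchanged.
    """

    start: int
    stop: int
    regime: str  # "excitation" | "precession"


def _validate_events(seq: Sequence) -> None:
    # SeqBlock already validates containment at construction; re-check in
    # case durations were mutated afterwards.
    tol = 1e-9
    for i, b in enumerate(seq.blocks):
        for name in ("rf", "gx", "gy", "gz", "adc"):
            ev = getattr(b, name)
            if ev is not None and ev.end > b.duration + tol:
                raise ValueError(
                    f"block {i}: {name} event extends beyond block duration"
                )


def _merge_times(times: np.ndarray, tol: float = TIME_MERGE_TOL) -> np.ndarray:
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return times
    keep = np.ones(len(times), dtype=bool)
    keep[1:] = np.diff(times) > tol
    return times[keep]


def critical_times(seq: Sequence, config: SimConfig) -> np.ndarray:
    """Sorted node times required to simulate ``seq`` exactly.

    Includes block boundaries, every gradient vertex, RF raster nodes at
    spacing <= ``dt_rf`` across each pulse, every ADC sample time, and
    fill-in nodes so no gap exceeds ``dt``.  Duplicates within 1e-12 s
    are merged.
    """
    _validate_events(seq)
    starts = seq.block_starts
    pieces = [starts]
    for i, b in enumerate(seq.blocks):
        t0 = starts[i]
        for g in b.gradients():
            pieces.append(t0 + g.times)
        if b.rf is not None:
            rf = b.rf
            amp = rf.amplitude
            # boundaries where the sample-and-hold envelope actually
            # changes; runs of equal samples carry no field transition,
            # so the node set depends only on the field, not on how
            # finely the pulse happens to be rasterized
            chg = np.nonzero(amp[1:] != amp[:-1])[0] + 1
            edges = np.concatenate([[0], chg, [len(amp)]])
            pieces.append(t0 + rf.delay + edges * rf.raster)
            # subdivide nonzero constant runs at spacing <= dt_rf
            for a, e in zip(edges[:-1], edges[1:]):
                if amp[a] == 0:
                    continue
                span = (e - a) * rf.raster
                nsub = int(np.ceil(span / config.dt_rf))
                if nsub > 1:
                    sub = (
                        rf.delay
                        + a * rf.raster
                        + span * np.arange(1, nsub) / nsub
                    )
                    pieces.append(t0 + sub)
        if b.adc is not None:
            pieces.append(t0 + b.adc.sample_times)
    t = _merge_times(np.concatenate(pieces))
    # cap node spacing at dt (required when the phantom moves; harmless
    # otherwise since gradients are handled exactly on their vertices)
    gaps = np.diff(t)
    if np.any(gaps > config.dt * (1 + 1e-9)):
        fill = []
        for i in np.nonzero(gaps > config.dt * (1 + 1e-9))[0]:
            nsub = int(np.ceil(gaps[i] / config.dt))
            fill.append(t[i] + gaps[i] * np.arange(1, nsub) / nsub)
        t = _merge_times(np.concatenate([t] + fill))
    return t


def _sample_block_fields(block: SeqBlock, t_rel: np.ndarray):
    """Fields at times ``t_rel`` (relative to block start).

    RF is sample-and-hold on its raster; gradients interpolate linearly
    between vertices and vanish outside the vertex span.
    """
    b1 = np.zeros(len(t_rel), dtype=complex)
    if block.rf is not None:
        rf = block.rf
        tl = t_rel - rf.delay
        idx = np.floor(tl / rf.raster + 1e-9).astype(int)
        inside = (idx >= 0) & (idx < len(rf.amplitude)) & (tl > -1e-12)
        if np.any(inside):
            env = rf.amplitude[idx[inside]]
            carrier = np.exp(
                1j * (rf.phase_offset + rf.freq_offset * tl[inside])
            )
            b1[inside] = env * carrier
    grads = np.zeros((len(t_rel), 3))
    for g in block.gradients():
        ax = "xyz".index(g.axis)
        vals = np.interp(t_rel, g.times, g.amplitudes)
        outside = (t_rel < g.times[0] - 1e-12) | (t_rel > g.times[-1] + 1e-12)
        vals[outside] = 0.0
        grads[:, ax] += vals
    return b1, grads


def discretize(
    seq: Sequence, config: SimConfig, scanner: Scanner | None = None
) -> DiscreteSequence:
    """Sample the sequence on its critical time nodes.

    If ``scanner`` is given, gradient amplitude and slew limits are
    validated first.
    """
    if scanner is not None:
        seq.validate(scanner)
    t = critical_times(seq, config)
    starts = seq.block_starts
    n = len(t)
    B1 = np.zeros(n, dtype=complex)
    G = np.zeros((n, 3))
    # node -> owning block (nodes on a boundary belong to the later block,
    # matching the sample-and-hold reading of the fields)
    owner = np.clip(np.searchsorted(starts, t + 1e-12) - 1, 0, len(seq.blocks) - 1)
    for i, b in enumerate(seq.blocks):
        sel = owner == i
        if not np.any(sel):
            continue
        b1, g = _sample_block_fields(b, t[sel] - starts[i])
        B1[sel] = b1
        G[sel] = g
    adc = np.zeros(n, dtype=bool)
    groups = []
    for i, t0, ev in seq.adc_events():
        st = t0 + ev.sample_times
        idx = np.searchsorted(t, st - TIME_MERGE_TOL)
        ok = (idx < n) & (np.abs(t[np.minimum(idx, n - 1)] - st) <= 1e-9)
        if not np.all(ok):
            raise RuntimeError("internal error: ADC sample time missing a node")
        adc[idx] = True
        groups.append(idx)
    return DiscreteSequence(t, B1, G[:, 0], G[:, 1], G[:, 2], adc, groups)


def _protected_intervals(dseq: DiscreteSequence):
    """Node intervals a block boundary must not fall inside.

    A boundary at node j splits steps j-1 | j.  We protect (a, b+1) for
    each maximal run of nonzero-B1 nodes [a, b] (keeping a whole RF pulse
    in one regime) and (a, b] for each ADC event's sample span (keeping
    one readout inside one simulation block).
    """
    iv = []
    nz = np.nonzero(np.abs(dseq.B1) > 0)[0]
    if nz.size:
        brk = np.nonzero(np.diff(nz) > 1)[0]
        run_starts = np.concatenate([[nz[0]], nz[brk + 1]])
        run_ends = np.concatenate([nz[brk], [nz[-1]]])
        for a, b in zip(run_starts, run_ends):
            iv.append((int(a), int(b) + 2))  # forbid j in (a, b+1]
    for g in dseq.adc_node_groups:
        iv.append((int(g[0]), int(g[-1]) + 1))  # forbid j in (a, b]
    return iv


def partition(dseq: DiscreteSequence, config: SimConfig) -> list:
    """Split the node axis into ~equal simulation blocks.

    Returns :class:`SimBlock` spans covering all steps exactly once.
    Boundaries are pushed forward so they never bisect an RF pulse's node
    run or an ADC event's sample span.  A block is tagged ``excitation``
    iff any of its steps starts at a node with nonzero B1.
    """
    n_steps = dseq.n_nodes - 1
    if n_steps < 1:
        return []
    nb = config.n_blocks
    if nb > n_steps:
        warnings.warn(
            f"n_blocks={nb} exceeds step count {n_steps}; clamping",
            stacklevel=2,
        )
        nb = n_steps
    bounds = np.round(np.linspace(0, n_steps, nb + 1)).astype(int)
    protected = _protected_intervals(dseq)
    for k in range(1, nb):
        j = bounds[k]
        for a, b in protected:
            if a < j < b:
                j = b
        bounds[k] = min(j, n_steps)
    bounds = np.unique(bounds)
    blocks = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        regime = (
            "excitation"
            if np.any(np.abs(dseq.B1[i0:i1]) > 0)
            else "precession"
        )
        blocks.append(SimBlock(int(i0), int(i1), regime))
    return blocks
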