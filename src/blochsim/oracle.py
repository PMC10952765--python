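"""Dense-timestep reference Bloch integrator.

A deliberately simple solver used to validate the sequence-aware engine:
uniform fine time steps over the whole sequence, no regime switching, no
trapezoidal shortcut, rotations applied as explicit 3x3 Rodrigues
matrices.  It shares only the core data types with the production
kernels, so agreement between the two is evidence of correctness rather
than a tautology.

Fields are sampled at the midpoint of each step, which keeps the
constant-field approximation second-order accurate for shaped RF and
exact for piecewise-linear gradients.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GAMMA,
    Phantom,
    RawData,
    Readout,
    Scanner,
    Sequence,
    spin_position,
)

__all__ = ["reference_simulate", "convergence_order", "rotate_rodrigues"]


def rotate_rodrigues(mvec: np.ndarray, bx, by, bz, dt: float, gamma: float):
    """Rotate magnetization vectors about the field by phi = -gamma*|B|*dt.

    ``mvec`` is (n, 3); the field components broadcast against n.
    """
    bx = np.broadcast_to(np.asarray(bx, dtype=float), mvec.shape[:1]).copy()
    by = np.broadcast_to(np.asarray(by, dtype=float), mvec.shape[:1]).copy()
    bz = np.broadcast_to(np.asarray(bz, dtype=float), mvec.shape[:1]).copy()
    B = np.sqrt(bx**2 + by**2 + bz**2)
    safe = np.where(B == 0.0, 1.0, B)
    n = np.column_stack([bx, by, bz]) / safe[:, None]
    phi = -gamma * B * dt
    cosp = np.cos(phi)[:, None]
    sinp = np.sin(phi)[:, None]
    ndotm = np.sum(n * mvec, axis=1, keepdims=True)
    out = mvec * cosp + np.cross(n, mvec) * sinp + n * ndotm * (1.0 - cosp)
    return np.where(B[:, None] == 0.0, mvec, out)


def _sample_sequence_fields(seq: Sequence, times: np.ndarray):
    """B1 (complex) and gradients (n, 3) at arbitrary absolute times.

    Independent re-implementation of the event semantics: RF envelopes
    are sample-and-hold on their raster, gradients piecewise linear
    between vertices and zero outside their span.
    """
    starts = seq.block_starts
    b1 = np.zeros(len(times), dtype=complex)
    g = np.zeros((len(times), 3))
    owner = np.clip(
        np.searchsorted(starts, times, side="right") - 1, 0, len(seq.blocks) - 1
    )
    for i, blk in enumerate(seq.blocks):
        sel = owner == i
        if not np.any(sel):
            continue
        tr = times[sel] - starts[i]
        if blk.rf is not None:
            rf = blk.rf
            idx = np.floor((tr - rf.delay) / rf.raster).astype(int)
            ok = (idx >= 0) & (idx < len(rf.amplitude))
            vals = np.zeros(len(tr), dtype=complex)
            vals[ok] = rf.amplitude[idx[ok]] * np.exp(
                1j
                * (rf.phase_offset + rf.freq_offset * (tr[ok] - rf.delay))
            )
            b1[sel] = vals
        gblk = np.zeros((len(tr), 3))
        for ev in blk.gradients():
            ax = "xyz".index(ev.axis)
            v = np.interp(tr, ev.times, ev.amplitudes, left=0.0, right=0.0)
            v[(tr < ev.times[0]) | (tr > ev.times[-1])] = 0.0
            gblk[:, ax] += v
        g[sel] = gblk
    return b1, g


def reference_simulate(
    phantom: Phantom,
    seq: Sequence,
    scanner: Scanner | None = None,
    step: float = 1e-6,
) -> RawData:
    """Brute-force simulation at uniform step size.

    The time grid is ``arange(0, duration, step)`` plus the exact ADC
    sample times.  Every step applies the exact rotation generated by
    the midpoint field followed by exact relaxation.  Returns raw data
    with one readout per ADC event (demodulation phase applied); no
    trajectory is attached.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    scanner = scanner or Scanner()
    gamma = scanner.gamma
    dur = seq.duration
    grid = np.arange(0.0, dur + step / 2, step)
    if grid[-1] < dur:
        grid = np.append(grid, dur)
    adc_events = seq.adc_events()
    adc_times = [t0 + ev.sample_times for _, t0, ev in adc_events]
    all_adc = (
        np.concatenate(adc_times) if adc_times else np.zeros(0)
    )
    t = np.unique(np.concatenate([grid, all_adc]))
    mid = 0.5 * (t[:-1] + t[1:])
    dt = np.diff(t)
    b1_mid, g_mid = _sample_sequence_fields(seq, mid)

    n = phantom.n_spins
    mvec = np.zeros((n, 3))
    mvec[:, 2] = phantom.M0
    dw_over_gamma = phantom.dw / gamma
    static = phantom.motion is None
    if static:
        px, py, pz = phantom.x, phantom.y, phantom.z

    # signal sampled at node times: map sample time -> node index
    sample_at = {}
    for ti in all_adc:
        sample_at.setdefault(int(np.searchsorted(t, ti - 1e-12)), None)
    signal_at_node = {}

    # cache relaxation factors for the (dominant) uniform step
    e2_cache = {}

    def relax_factors(h):
        key = round(h * 1e15)
        if key not in e2_cache:
            e2_cache[key] = (
                np.exp(-h / phantom.T2),
                np.exp(-h / phantom.T1),
            )
        return e2_cache[key]

    if 0 in sample_at:
        signal_at_node[0] = complex(np.sum(mvec[:, 0] + 1j * mvec[:, 1]))
    for i in range(len(mid)):
        h = dt[i]
        if h == 0.0:
            continue
        if static:
            x, y, z = px, py, pz
        else:
            x, y, z = spin_position(phantom, mid[i])
        bz = g_mid[i, 0] * x + g_mid[i, 1] * y + g_mid[i, 2] * z + dw_over_gamma
        mvec = rotate_rodrigues(mvec, b1_mid[i].real, b1_mid[i].imag, bz, h, gamma)
        e2, e1 = relax_factors(h)
        mvec[:, 0] *= e2
        mvec[:, 1] *= e2
        mvec[:, 2] = mvec[:, 2] * e1 + phantom.M0 * (1.0 - e1)
        node = i + 1
        if node in sample_at:
            signal_at_node[node] = complex(np.sum(mvec[:, 0] + 1j * mvec[:, 1]))

    readouts = []
    for (_, t0, ev), st in zip(adc_events, adc_times):
        nodes = np.searchsorted(t, st - 1e-12)
        data = np.asarray(
            [signal_at_node[int(nd)] for nd in nodes], dtype=complex
        ) * np.exp(-1j * ev.phase)
        readouts.append(Readout(st, data, None))
    header = dict(seq.definitions)
    header["solver"] = f"reference_step_{step:g}"
    return RawData(readouts, header)


def convergence_order(
    b1_of_t,
    duration: float,
    steps,
    gamma: float = GAMMA,
    ref_refine: int = 16,
) -> float:
    """Estimated global convergence order of the excitation splitting.

    Integrates a single relaxation-free spin through the shaped pulse
    ``b1_of_t`` (callable, returns complex B1 in T) with the production
    excitation kernel at each step size, sampling the envelope at step
    midpoints, and compares the final state against the same integration
    at ``min(steps)/ref_refine`` performed with the independent
    Rodrigues-matrix rotation.  Returns the log-log slope of the error.
    """
    from .kernels import Mag, apply_spinor, spinor_from_field

    steps = sorted(steps, reverse=True)
    if len(steps) < 2:
        raise ValueError("need at least two step sizes")

    def run_kernel(h: float) -> np.ndarray:
        nsteps = int(round(duration / h))
        tm = (np.arange(nsteps) + 0.5) * (duration / nsteps)
        m = Mag(np.zeros(1, complex), np.ones(1))
        for ti in tm:
            s = spinor_from_field(b1_of_t(ti), 0.0, duration / nsteps, gamma)
            m = apply_spinor(s, m)
        return np.asarray([m.xy[0].real, m.xy[0].imag, m.z[0]])

    def run_reference(h: float) -> np.ndarray:
        nsteps = int(round(duration / h))
        tm = (np.arange(nsteps) + 0.5) * (duration / nsteps)
        mv = np.asarray([[0.0, 0.0, 1.0]])
        for ti in tm:
            b1 = complex(b1_of_t(ti))
            mv = rotate_rodrigues(
                mv, b1.real, b1.imag, 0.0, duration / nsteps, gamma
            )
        return mv[0]

    ref = run_reference(min(steps) / ref_refine)
    errs = np.asarray(
        [np.linalg.norm(run_kernel(h) - ref) for h in steps], dtype=float
    )
    # roundoff floor: the reference itself accumulates ~eps per step, so
    # errors below that are noise and a fitted slope would be meaningless
    ref_nsteps = int(round(duration / (min(steps) / ref_refine)))
    floor = 4.0 * np.finfo(float).eps * ref_nsteps
    if np.any(errs <= 0) or np.max(errs) < floor:
        return np.inf
    slope = np.polyfit(np.log(steps), np.log(errs), 1)[0]
    return float(slope)
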