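"""Image reconstruction and fingerprint matching.

Cartesian EPI is reconstructed by reordering the serpentine readout into
a k-space matrix and applying a centered 2-D inverse FFT.  Arbitrary
trajectories (spiral, radial) use the direct adjoint ("conjugate phase")
operator with optional ramp density compensation.

The fingerprinting tools simulate idealized dictionary atoms with the
same SU(2) kernels as the full solver, normalize them, and match voxel
signals by the maximum modulus of the complex inner product.
"""

from __future__ import annotations

import numpy as np

from .core import Mag, RawData
from .kernels import apply_spinor, relax, rotation_spinor
from .seqdesign import MRFSchedule

__all__ = [
    "recon_cartesian_epi",
    "recon_adjoint",
    "fingerprint_simulate",
    "build_dictionary",
    "match_fingerprints",
    "mad",
]

#: Default dictionary grids (s): T1 300..2500 ms step 10, T2 40..350 ms step 4.
DEFAULT_T1_GRID = np.arange(300, 2501, 10) * 1e-3
DEFAULT_T2_GRID = np.arange(40, 351, 4) * 1e-3


def recon_cartesian_epi(raw: RawData, n: int | None = None) -> np.ndarray:
    """Reconstruct a single-shot EPI acquisition.

    Readout ``j`` fills k-space row ``ky = (j - n/2)/fov``; odd rows were
    acquired with reversed polarity and are flipped back.  Returns the
    complex ``n x n`` image (row index = y, column index = x).
    """
    if n is None:
        n = int(raw.header.get("matrix", len(raw.readouts)))
    if len(raw.readouts) != n:
        raise ValueError(
            f"expected {n} readouts for an n={n} EPI, got {len(raw.readouts)}"
        )
    K = np.zeros((n, n), dtype=complex)
    for j, ro in enumerate(raw.readouts):
        if len(ro.samples) != n:
            raise ValueError(f"readout {j} has {len(ro.samples)} samples != {n}")
        K[j] = ro.samples[::-1] if j % 2 else ro.samples
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(K)))


def recon_adjoint(
    raw: RawData,
    fov: float | None = None,
    n: int | None = None,
    weights: str = "uniform",
    chunk: int = 4096,
) -> np.ndarray:
    """Direct adjoint reconstruction on an ``n x n`` grid.

    Evaluates ``img(r) = (1/N) * sum_j w_j s_j exp(+2i*pi*k_j . r)`` —
    the adjoint of the signal model ``s(k) = sum_r m(r) exp(-2i*pi*k.r)``.
    ``weights='ramp'`` applies |k| density compensation (appropriate for
    radial and spiral sampling); ``'uniform'`` applies none.
    """
    fov = float(raw.header["fov"]) if fov is None else fov
    n = int(raw.header["matrix"]) if n is None else n
    if any(ro.traj is None for ro in raw.readouts):
        raise ValueError("adjoint recon needs a k-space trajectory per readout")
    k = np.concatenate([ro.traj[:, :2] for ro in raw.readouts])
    s = np.concatenate([np.asarray(ro.samples) for ro in raw.readouts])
    if weights == "ramp":
        w = np.linalg.norm(k, axis=1)
        mean = w.mean()
        w = w / mean if mean > 0 else np.ones_like(w)
    elif weights == "uniform":
        w = np.ones(len(s))
    else:
        raise ValueError("weights must be 'uniform' or 'ramp'")
    sw = s * w
    coords = (np.arange(n) - n // 2) * fov / n
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    img = np.zeros((n, n), dtype=complex)
    for i0 in range(0, len(sw), chunk):
        sl = slice(i0, i0 + chunk)
        phase = 2j * np.pi * (
            X[..., None] * k[sl, 0] + Y[..., None] * k[sl, 1]
        )
        img += np.exp(phase) @ sw[sl]
    return img / len(sw)


def fingerprint_simulate(
    T1,
    T2,
    schedule: MRFSchedule,
    M0: float = 1.0,
) -> np.ndarray:
    """Idealized per-voxel bSSFP fingerprints for the given schedule.

    Pulses are instantaneous rotations at their nominal centers: an
    inversion, relaxation over TI, then per TR an excitation with the
    scheduled flip/phase, relaxation to TE where the demodulated echo is
    recorded, and relaxation over the remaining TR - TE.  On-resonance
    spins at the gradient echo (the balanced condition) are assumed.

    ``T1``/``T2`` may be arrays (one atom per entry); returns a complex
    array of shape ``(n_atoms, n_tr)``.
    """
    T1 = np.atleast_1d(np.asarray(T1, dtype=float))
    T2 = np.atleast_1d(np.asarray(T2, dtype=float))
    if len(T1) != len(T2):
        raise ValueError("T1 and T2 must have equal length")
    n_atoms = len(T1)
    M0v = np.full(n_atoms, float(M0))
    m = Mag(np.zeros(n_atoms, dtype=complex), M0v.copy())
    m = apply_spinor(rotation_spinor(np.pi), m)
    m = relax(m, schedule.TI, T1, T2, M0v)
    out = np.empty((n_atoms, schedule.n_tr), dtype=complex)
    phases = schedule.rf_phases
    for k in range(schedule.n_tr):
        m = apply_spinor(rotation_spinor(schedule.flip_angles[k], phases[k]), m)
        m = relax(m, schedule.TE, T1, T2, M0v)
        out[:, k] = m.xy * np.exp(-1j * phases[k])
        m = relax(m, schedule.TRs[k] - schedule.TE, T1, T2, M0v)
    return out


def build_dictionary(
    schedule: MRFSchedule,
    t1_grid: np.ndarray | None = None,
    t2_grid: np.ndarray | None = None,
    require_t2_le_t1: bool = False,
):
    """All (T1, T2) grid combinations as unit-norm fingerprints.

    Returns ``(atoms, params)``: atoms ``(n_atoms, n_tr)`` complex with
    unit L2 norm per row, params ``(n_atoms, 2)`` holding (T1, T2) in s.
    ``require_t2_le_t1`` drops the unphysical T2 > T1 corner.
    """
    t1_grid = DEFAULT_T1_GRID if t1_grid is None else np.asarray(t1_grid)
    t2_grid = DEFAULT_T2_GRID if t2_grid is None else np.asarray(t2_grid)
    T1, T2 = np.meshgrid(t1_grid, t2_grid, indexing="ij")
    params = np.column_stack([T1.ravel(), T2.ravel()])
    if require_t2_le_t1:
        params = params[params[:, 1] <= params[:, 0]]
    atoms = fingerprint_simulate(params[:, 0], params[:, 1], schedule)
    norms = np.linalg.norm(atoms, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return atoms / norms, params


def match_fingerprints(
    signals: np.ndarray,
    atoms: np.ndarray,
    params: np.ndarray,
    mask_frac: float = 0.05,
):
    """Dictionary matching by maximum |inner product|.

    ``signals`` is ``(n_vox, n_tr)``.  Voxels whose first-frame magnitude
    falls below ``mask_frac`` of the maximum are masked out (returned
    maps are 0 there).  Ties resolve to the lowest atom index.

    Returns ``(t1_map, t2_map, mask)`` as 1-D arrays over voxels.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=complex))
    if signals.shape[1] != atoms.shape[1]:
        raise ValueError("signal and dictionary lengths differ")
    first = np.abs(signals[:, 0])
    mask = first >= mask_frac * first.max()
    t1 = np.zeros(len(signals))
    t2 = np.zeros(len(signals))
    if np.any(mask):
        sig = signals[mask]
        norms = np.linalg.norm(sig, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        scores = np.abs((sig / norms) @ np.conj(atoms).T)
        best = np.argmax(scores, axis=1)
        t1[mask] = params[best, 0]
        t2[mask] = params[best, 1]
    return t1, t2, mask


def mad(x: np.ndarray, xref: np.ndarray) -> float:
    """Mean absolute difference in percent of the reference peak.

    Both signals are scaled by ``max |xref|`` before comparison, so the
    result is ``100 * mean(|x - xref|) / max(|xref|)``.
    """
    x = np.asarray(x).ravel()
    xref = np.asarray(xref).ravel()
    if x.shape != xref.shape:
        raise ValueError("signals must have equal length")
    peak = np.max(np.abs(xref))
    if peak == 0:
        raise ValueError("reference signal is identically zero")
    return float(100.0 * np.mean(np.abs(x - xref)) / peak)
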