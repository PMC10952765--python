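"""Regime solvers for the operator-splitting Bloch integrator.

Two specialized kernels implement the two sequence regimes:

* **Excitation** — each step applies the exact rotation generated by the
  (constant) effective field, stored as an SU(2) spinor, followed by the
  exact relaxation update.  For piecewise-constant RF the rotation is
  exact; for shaped pulses the splitting converges at third order
  locally (second order globally).
* **Precession** — with B1 = 0 every rotation is about z, so the whole
  block reduces to a phase exp(i*phi) with
  ``phi = -gamma * int Bz dt`` accumulated by the trapezoidal rule,
  which is *exact* for piecewise-linear gradients and static spins.

Sign convention: the accumulated phase is ``phi = -gamma*B*dt``, so a
positive off-resonance accrues negative phase.
"""

from __future__ import annotations

import numpy as np

from .core import DiscreteSequence, GAMMA, Mag, Phantom, Spinor, spin_position

__all__ = [
    "spinor_from_field",
    "rotation_spinor",
    "apply_spinor",
    "relax",
    "excitation_step",
    "precession_block",
]


def spinor_from_field(B1, Bz, dt: float, gamma: float = GAMMA) -> Spinor:
    """Spinor of the rotation generated by a constant field over ``dt``.

    ``B1`` is the complex transverse field (T), ``Bz`` the longitudinal
    component (T); both may be arrays (broadcast together).  A zero field
    yields the identity spinor.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    B1 = np.asarray(B1, dtype=complex)
    Bz = np.asarray(Bz, dtype=float)
    B = np.sqrt(np.abs(B1) ** 2 + Bz**2)
    phi = -gamma * B * dt
    safe = np.where(B == 0, 1.0, B)
    n_xy = B1 / safe
    n_z = Bz / safe
    half = phi / 2.0
    sin_h = np.sin(half)
    alpha = np.cos(half) - 1j * n_z * sin_h
    beta = -1j * n_xy * sin_h
    # zero field: phi = 0 already gives (1, 0); keep explicit for clarity
    alpha = np.where(B == 0, 1.0 + 0j, alpha)
    beta = np.where(B == 0, 0.0 + 0j, beta)
    return Spinor(alpha, beta)


def rotation_spinor(flip: float, phase: float = 0.0) -> Spinor:
    """Spinor of an ideal (instantaneous) RF rotation.

    Equivalent to :func:`spinor_from_field` with a transverse field along
    ``exp(i*phase)`` whose amplitude-duration product gives ``flip``
    (gamma*B1*dt = flip).  Used for idealized pulses in dictionary
    simulation.
    """
    return spinor_from_field(np.exp(1j * phase), 0.0, float(flip), gamma=1.0)


def apply_spinor(s: Spinor, m: Mag) -> Mag:
    """Rotate magnetization by a spinor (elementwise).

    Implements the spin-domain rotation
    ``Mxy+ = 2*conj(a)*b*Mz + conj(a)^2*Mxy - b^2*conj(Mxy)`` and
    ``Mz+  = (|a|^2-|b|^2)*Mz - 2*Re(a*b*conj(Mxy))``.
    """
    a, b = s.alpha, s.beta
    ac = np.conj(a)
    xy = 2.0 * ac * b * m.z + ac**2 * m.xy - b**2 * np.conj(m.xy)
    z = (np.abs(a) ** 2 - np.abs(b) ** 2) * m.z - 2.0 * np.real(
        a * b * np.conj(m.xy)
    )
    return Mag(xy, z)


def relax(m: Mag, dt: float, T1, T2, M0) -> Mag:
    """Exact relaxation update over ``dt``.

    ``Mxy`` decays with T2; ``Mz`` recovers toward ``M0`` with T1.
    Infinite relaxation times are allowed (no decay / no recovery).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    e2 = np.exp(-dt / np.asarray(T2, dtype=float))
    e1 = np.exp(-dt / np.asarray(T1, dtype=float))
    return Mag(m.xy * e2, m.z * e1 + np.asarray(M0, dtype=float) * (1.0 - e1))


def excitation_step(
    m: Mag,
    phantom: Phantom,
    B1: complex,
    G,
    dt: float,
    t: float,
    gamma: float = GAMMA,
) -> Mag:
    """One splitting step of the excitation regime.

    Per spin the longitudinal field is ``Bz = G . x(t) + dw/gamma`` (the
    off-resonance contributes during excitation too, so slice-profile
    effects of off-resonance are captured).  The rotation is applied
    first, then relaxation, mirroring the splitting order.

    ``t`` is the time at which spin positions are evaluated; callers
    integrating over a step should pass the step midpoint.
    """
    x, y, z = spin_position(phantom, t)
    gx, gy, gz = G
    Bz = gx * x + gy * y + gz * z + phantom.dw / gamma
    s = spinor_from_field(B1, Bz, dt, gamma)
    m = apply_spinor(s, m)
    return relax(m, dt, phantom.T1, phantom.T2, phantom.M0)


def _cumtrapz0(values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral along axis 0, starting at 0."""
    dt = np.diff(t)
    if values.ndim == 1:
        inc = dt * 0.5 * (values[:-1] + values[1:])
    else:
        inc = dt[:, None] * 0.5 * (values[:-1] + values[1:])
    out = np.zeros_like(values)
    np.cumsum(inc, axis=0, out=out[1:])
    return out


def precession_block(
    m: Mag, phantom: Phantom, dsub: DiscreteSequence, gamma: float = GAMMA
):
    """Evolve through a precession (B1 = 0) span and sample the signal.

    Per spin the phase at node k is the trapezoidal integral
    ``phi_k = -gamma * int_{t0}^{tk} (G . x + dw/gamma) dt`` — exact for
    piecewise-linear gradients when the spins are static.  Transverse
    decay is tracked per node so ADC samples carry the correct T2
    weighting; Mz relaxation is applied once over the block (precession
    does not couple Mz, so this is identical to per-step application).

    Returns the state at the final node and the complex signal
    (sum of Mxy over spins) at every adc-flagged node after the first.
    """
    if np.any(np.abs(dsub.B1) > 0):
        raise RuntimeError("regime violation: nonzero B1 inside precession block")
    t = dsub.t
    n = len(t)
    if n < 2:
        return m.copy(), np.zeros(0, dtype=complex)
    elapsed = t - t[0]
    sample_idx = np.nonzero(dsub.adc[1:])[0] + 1  # exclude the shared first node

    if phantom.motion is None:
        # separable fast path: per-node scalar gradient integrals
        Ix = _cumtrapz0(dsub.Gx, t)
        Iy = _cumtrapz0(dsub.Gy, t)
        Iz = _cumtrapz0(dsub.Gz, t)
        need = np.concatenate([sample_idx, [n - 1]])
        phase = -gamma * (
            np.outer(Ix[need], phantom.x)
            + np.outer(Iy[need], phantom.y)
            + np.outer(Iz[need], phantom.z)
        ) - np.outer(elapsed[need], phantom.dw)
    else:
        Bz = np.empty((n, phantom.n_spins))
        for k in range(n):
            x, y, z = spin_position(phantom, t[k])
            Bz[k] = dsub.Gx[k] * x + dsub.Gy[k] * y + dsub.Gz[k] * z
        Bz += phantom.dw[None, :] / gamma
        phi_all = -gamma * _cumtrapz0(Bz, t)
        need = np.concatenate([sample_idx, [n - 1]])
        phase = phi_all[need]

    decay = np.exp(np.outer(-elapsed[need], 1.0 / phantom.T2))
    xy_nodes = m.xy[None, :] * np.exp(1j * phase) * decay
    samples = xy_nodes[:-1].sum(axis=1)
    xy_end = xy_nodes[-1]
    total = elapsed[-1]
    e1 = np.exp(-total / phantom.T1)
    z_end = m.z * e1 + phantom.M0 * (1.0 - e1)
    return Mag(xy_end, z_end), samples
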