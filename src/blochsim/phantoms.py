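"""Built-in numerical phantoms.

These generators reproduce the standard 2-D validation objects for EPI
artifact studies — a four-segment column of spins, two concentric
circles with an off-resonant core, and a multi-ellipse pseudo-brain —
plus a helper that attaches a rigid linear motion field.

Segment and disc membership uses half-open intervals / strict-interior
tests so every spin belongs to exactly one region.  Default spin spacing
is 1 mm.
"""

from __future__ import annotations

import numpy as np

from .core import Phantom

__all__ = [
    "column_phantom",
    "circles_phantom",
    "pseudo_brain_phantom",
    "with_linear_motion",
    "builtin_phantom",
]


def column_phantom(spacing: float = 1e-3) -> Phantom:
    """Column of spins along y: four contiguous 50 mm segments.

    Segments (from -100 mm upward, half-open) carry M0 = [1, 0.5, 1, 0.5]
    and T1 = T2 = [100, 50, 100, 50] ms; x = z = 0, no off-resonance.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    seg_len = 50e-3
    y = np.arange(-2 * seg_len, 2 * seg_len - spacing / 2, spacing)
    # half-open segments; the tiny nudge keeps grid points that land
    # exactly on a boundary in the upper segment despite float rounding
    seg = np.clip(
        np.floor((y + 2 * seg_len) / seg_len + 1e-6).astype(int), 0, 3
    )
    M0 = np.array([1.0, 0.5, 1.0, 0.5])[seg]
    T = np.array([100e-3, 50e-3, 100e-3, 50e-3])[seg]
    zero = np.zeros_like(y)
    return Phantom(zero, y, zero.copy(), M0, T, T.copy(), zero.copy(),
                   name="column")


def circles_phantom(spacing: float = 1e-3) -> Phantom:
    """Two concentric discs: outer R = 50 mm, inner r = 25 mm.

    The inner disc is off-resonant by 200 rad/s with T1 = T2 = 50 ms; the
    annulus is on-resonance with T1 = T2 = 100 ms.  M0 = 1 everywhere.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    R, r = 50e-3, 25e-3
    coords = np.arange(-R, R + spacing / 2, spacing)
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    rad2 = X**2 + Y**2
    inside = rad2 < R**2
    x, y = X[inside], Y[inside]
    inner = (x**2 + y**2) < r**2
    T = np.where(inner, 50e-3, 100e-3)
    dw = np.where(inner, 200.0, 0.0)
    return Phantom(
        x, y, np.zeros_like(x), np.ones_like(x), T, T.copy(), dw,
        name="circles",
    )


# tissue classes of the pseudo-brain: (M0, T1 s, T2 s) — nominal white
# matter, gray matter and CSF values at 1.5 T
_BRAIN_TISSUES = {
    "wm": (0.8, 0.8, 0.08),
    "gm": (0.9, 1.3, 0.11),
    "csf": (1.0, 3.0, 0.3),
}


def pseudo_brain_phantom(
    spacing: float = 1e-3,
    seed: int = 0,
    offres_range: tuple | None = None,
) -> Phantom:
    """Synthetic multi-ellipse 2-D head with three tissue classes.

    A deterministic (seeded) stand-in for a segmented anatomical brain:
    an elliptical white-matter head, randomly placed gray-matter blobs
    and CSF ventricles.  ``offres_range = (lo, hi)`` (rad/s) adds a
    smooth off-resonance field spanning exactly that range.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    a, b = 80e-3, 95e-3  # head semi-axes
    xs = np.arange(-a, a + spacing / 2, spacing)
    ys = np.arange(-b, b + spacing / 2, spacing)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    head = (X / a) ** 2 + (Y / b) ** 2 < 1.0
    x, y = X[head], Y[head]

    tissue = np.zeros(len(x), dtype=int)  # 0 = wm
    # gray-matter rim plus random cortical blobs
    rim = (x / a) ** 2 + (y / b) ** 2 > 0.75
    tissue[rim] = 1
    for _ in range(6):
        cx = rng.uniform(-0.5 * a, 0.5 * a)
        cy = rng.uniform(-0.5 * b, 0.5 * b)
        rr = rng.uniform(8e-3, 16e-3)
        tissue[((x - cx) ** 2 + (y - cy) ** 2) < rr**2] = 1
    # CSF ventricles: two mirrored ellipses near the center
    for sx in (-1.0, 1.0):
        vx, vy = sx * 18e-3, 5e-3
        v = ((x - vx) / 12e-3) ** 2 + ((y - vy) / 25e-3) ** 2 < 1.0
        tissue[v] = 2

    props = np.array([_BRAIN_TISSUES[k] for k in ("wm", "gm", "csf")])
    M0, T1, T2 = props[tissue, 0], props[tissue, 1], props[tissue, 2]
    dw = np.zeros(len(x))
    if offres_range is not None:
        lo, hi = offres_range
        cx, cy = rng.uniform(-0.3 * a, 0.3 * a), rng.uniform(-0.3 * b, 0.3 * b)
        fieldmap = np.exp(-(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2) * 2.0)
        fieldmap = (fieldmap - fieldmap.min()) / np.ptp(fieldmap)
        dw = lo + (hi - lo) * fieldmap
    return Phantom(x, y, np.zeros_like(x), M0, T1, T2, dw, name="pseudo_brain")


def with_linear_motion(phantom: Phantom, vy: float) -> Phantom:
    """Attach a rigid displacement field u(x, t) = (0, vy*t, 0)."""

    def motion(x0, y0, z0, t):
        zero = np.zeros_like(x0)
        return zero, np.full_like(y0, vy * t), zero

    return Phantom(
        phantom.x, phantom.y, phantom.z, phantom.M0, phantom.T1, phantom.T2,
        phantom.dw, motion=motion if vy != 0.0 else None, name=phantom.name,
    )


def builtin_phantom(name: str, spacing: float = 1e-3, seed: int = 0) -> Phantom:
    """Look up a generator by name (used by the CLI)."""
    if name == "column":
        return column_phantom(spacing)
    if name == "circles":
        return circles_phantom(spacing)
    if name == "brain":
        return pseudo_brain_phantom(spacing, seed=seed)
    raise KeyError(f"unknown builtin phantom {name!r}")
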