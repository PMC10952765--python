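"""Shared fixtures.

The expensive simulations (dense-reference comparison, artifact studies)
are session-scoped so the acceptance tests and unit tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import blochsim as bs


@pytest.fixture(scope="session")
def scanner():
    return bs.Scanner()


@pytest.fixture(scope="session")
def epi_fixture_seq():
    """The reference experiment: single-shot GRE EPI, TE 100 ms,
    FOV 230 mm, 100 x 100 matrix."""
    return bs.epi_sequence(0.23, 100, 0.1)


@pytest.fixture(scope="session")
def column():
    return bs.column_phantom()


@pytest.fixture(scope="session")
def column_epi(column, epi_fixture_seq):
    """Engine and dense-reference signals for the column-phantom EPI."""
    raw = bs.simulate(column, epi_fixture_seq)
    ref = bs.reference_simulate(column, epi_fixture_seq, step=1e-6)
    sig = np.concatenate([r.samples for r in raw.readouts])
    refsig = np.concatenate([r.samples for r in ref.readouts])
    return {"raw": raw, "signal": sig, "reference": refsig}


@pytest.fixture(scope="session")
def circles_images(epi_fixture_seq):
    """Reconstructed EPI images of the circles phantom in four variants:
    off-resonant (dw = 200 rad/s core), on-resonance, annulus-only, and
    on-resonance with vy = 0.1 m/s motion.  2 mm spacing for runtime."""
    seq = epi_fixture_seq
    ph = bs.circles_phantom(spacing=2e-3)
    ph0 = bs.Phantom(ph.x, ph.y, ph.z, ph.M0, ph.T1, ph.T2,
                     np.zeros_like(ph.dw), name="circles0")
    annulus = ph.subset(np.nonzero(ph.dw == 0)[0])
    moving = bs.with_linear_motion(ph0, 0.1)

    def image(p):
        return bs.recon_cartesian_epi(bs.simulate(p, seq))

    return {
        "offres": image(ph),
        "onres": image(ph0),
        "annulus": image(annulus),
        "moving": image(moving),
        "echo_spacing": seq.definitions["echo_spacing"],
        "fov": seq.definitions["fov"],
        "n": seq.definitions["matrix"],
    }


def centroid_y(image: np.ndarray) -> float:
    """Intensity-weighted centroid along the row (y) axis, in pixels
    relative to the image center."""
    w = np.abs(image)
    ys = np.arange(image.shape[0]) - image.shape[0] // 2
    return float((w.sum(axis=1) * ys).sum() / w.sum())
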