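import numpy as np
import pytest

import blochsim as bs
from blochsim.core import RawData, Readout
from blochsim.recon import DEFAULT_T1_GRID, DEFAULT_T2_GRID, mad


class TestCartesianEPI:
    def test_point_source_location(self):
        fov, n = 0.2, 16
        dx = fov / n
        ph = bs.Phantom([3 * dx], [-2 * dx], [0.0], [1.0],
                        [np.inf], [np.inf], [0.0])
        raw = bs.simulate(ph, bs.epi_sequence(fov, n, 0.02))
        img = bs.recon_cartesian_epi(raw)
        iy, ix = np.unravel_index(np.argmax(np.abs(img)), img.shape)
        assert ix - n // 2 == 3
        assert iy - n // 2 == -2

    def test_wrong_readout_count(self):
        raw = RawData([Readout(np.zeros(4), np.zeros(4, complex))],
                      {"matrix": 16})
        with pytest.raises(ValueError, match="readouts"):
            bs.recon_cartesian_epi(raw)


class TestAdjoint:
    def test_point_source_spiral(self):
        fov, n = 0.2, 32
        dx = fov / n
        ph = bs.Phantom([4 * dx], [2 * dx], [0.0], [1.0],
                        [np.inf], [np.inf], [0.0])
        raw = bs.simulate(ph, bs.spiral_sequence(fov, n, 1e-4))
        img = bs.recon_adjoint(raw, weights="ramp")
        iy, ix = np.unravel_index(np.argmax(np.abs(img)), img.shape)
        assert abs(ix - n // 2 - 4) <= 1
        assert abs(iy - n // 2 - 2) <= 1

    def test_requires_trajectory(self):
        raw = RawData(
            [Readout(np.zeros(4), np.zeros(4, complex), None)],
            {"fov": 0.2, "matrix": 8},
        )
        with pytest.raises(ValueError, match="trajectory"):
            bs.recon_adjoint(raw)

    def test_unknown_weights(self):
        raw = bs.simulate(bs.column_phantom(spacing=50e-3),
                          bs.epi_sequence(0.2, 16, 0.02))
        with pytest.raises(ValueError, match="weights"):
            bs.recon_adjoint(raw, weights="bogus")

    def test_matches_fft_on_cartesian(self):
        # on a fully sampled Cartesian grid the adjoint equals the iFFT
        fov, n = 0.2, 16
        raw = bs.simulate(bs.column_phantom(spacing=20e-3),
                          bs.epi_sequence(fov, n, 0.02))
        img_fft = bs.recon_cartesian_epi(raw)
        img_adj = bs.recon_adjoint(raw) * n * n
        corr = np.abs(np.vdot(img_fft, img_adj)) / (
            np.linalg.norm(img_fft) * np.linalg.norm(img_adj)
        )
        assert corr > 0.999


class TestFingerprints:
    def test_shapes_and_scaling(self):
        sched = bs.mrf_schedule(30, seed=0)
        fp = bs.fingerprint_simulate([1.0, 0.5], [0.1, 0.05], sched)
        assert fp.shape == (2, 30)
        fp2 = bs.fingerprint_simulate([1.0], [0.1], sched, M0=2.0)
        assert fp2[0] == pytest.approx(2 * fp[0], abs=1e-14)

    def test_inversion_recovery_signature(self):
        # short-T1 tissue recovers faster from inversion: larger early signal
        sched = bs.mrf_schedule(10, seed=0)
        fp = bs.fingerprint_simulate([0.3, 2.5], [0.1, 0.1], sched)
        assert np.real(fp[0, 0] * np.conj(fp[1, 0])) != 0.0

    def test_dictionary_shape_and_norm(self):
        sched = bs.mrf_schedule(20, seed=0)
        atoms, params = bs.build_dictionary(sched)
        assert atoms.shape == (221 * 78, 20)
        assert params.shape == (221 * 78, 2)
        assert np.linalg.norm(atoms, axis=1) == pytest.approx(
            np.ones(len(atoms)), abs=1e-12
        )
        assert params[:, 0].min() == pytest.approx(0.3)
        assert params[:, 0].max() == pytest.approx(2.5)
        assert params[:, 1].min() == pytest.approx(0.04)
        assert params[:, 1].max() == pytest.approx(0.348)

    def test_physical_filter(self):
        sched = bs.mrf_schedule(5, seed=0)
        _, params = bs.build_dictionary(sched, require_t2_le_t1=True)
        assert np.all(params[:, 1] <= params[:, 0])
        assert len(params) < 221 * 78

    def test_matching_recovers_on_grid(self):
        sched = bs.mrf_schedule(40, seed=0)
        grid1 = np.asarray([0.5, 1.0, 1.5])
        grid2 = np.asarray([0.05, 0.1])
        atoms, params = bs.build_dictionary(sched, grid1, grid2)
        sig = bs.fingerprint_simulate([1.0, 0.5], [0.1, 0.05], sched) * 3.7
        t1, t2, mask = bs.match_fingerprints(sig, atoms, params)
        assert t1 == pytest.approx([1.0, 0.5])
        assert t2 == pytest.approx([0.1, 0.05])
        assert mask.all()

    def test_mask_suppresses_background(self):
        sched = bs.mrf_schedule(20, seed=0)
        atoms, params = bs.build_dictionary(
            sched, np.asarray([1.0]), np.asarray([0.1])
        )
        fg = bs.fingerprint_simulate([1.0], [0.1], sched)[0]
        sig = np.stack([fg, 1e-4 * fg])
        t1, t2, mask = bs.match_fingerprints(sig, atoms, params)
        assert mask.tolist() == [True, False]
        assert t1[1] == 0.0 and t2[1] == 0.0

    def test_engine_fingerprint_matches_dictionary(self):
        """Cross-validation: a full Bloch simulation of the bSSFP train is
        matched by the idealized dictionary at the true grid point."""
        sched = bs.mrf_schedule(60, seed=4)
        seq = bs.mrf_bssfp_sequence(sched, 0.23, 100)
        ph = bs.Phantom([0.0], [0.0], [0.0], [1.0], [1.0], [0.2], [0.0])
        raw = bs.simulate(ph, seq)
        fp = np.asarray([r.samples[50] for r in raw.readouts])[None, :]
        atoms, params = bs.build_dictionary(sched)
        t1, t2, _ = bs.match_fingerprints(fp, atoms, params)
        assert t1[0] == pytest.approx(1.0, abs=1e-12)
        assert t2[0] == pytest.approx(0.2, abs=1e-12)


class TestMAD:
    def test_zero_for_identical(self):
        x = np.asarray([1.0, 2.0, -1.0])
        assert mad(x, x) == 0.0

    def test_known_value(self):
        xref = np.asarray([0.0, 2.0])
        x = np.asarray([0.5, 2.0])
        assert mad(x, xref) == pytest.approx(100 * 0.25 / 2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mad(np.ones(3), np.zeros(3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mad(np.ones(3), np.ones(4))


def test_default_grids_match_printed_ranges():
    assert len(DEFAULT_T1_GRID) == 221
    assert len(DEFAULT_T2_GRID) == 78
    assert np.diff(DEFAULT_T1_GRID) == pytest.approx(
        np.full(220, 10e-3), abs=1e-12
    )
    assert np.diff(DEFAULT_T2_GRID) == pytest.approx(
        np.full(77, 4e-3), abs=1e-12
    )
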