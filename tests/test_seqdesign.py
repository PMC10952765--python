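import numpy as np
import pytest

import blochsim as bs
from blochsim.core import GAMMA
from blochsim.seqdesign import TINY_GOLDEN_ANGLE


class TestHardPulse:
    def test_amplitude_closed_form(self):
        blk = bs.hard_pulse(np.pi / 2, 0.5e-3)
        assert abs(blk.rf.amplitude[0]) == pytest.approx(
            (np.pi / 2) / (267.538e6 * 5e-4), rel=1e-5
        )

    def test_zero_flip(self):
        assert bs.hard_pulse(0.0, 1e-4).rf.amplitude[0] == 0.0

    def test_duration_amplitude_tradeoff(self):
        a1 = abs(bs.hard_pulse(np.pi / 2, 1e-4).rf.amplitude[0])
        a2 = abs(bs.hard_pulse(np.pi / 2, 2e-4).rf.amplitude[0])
        assert a1 == pytest.approx(2 * a2)

    def test_b1_limit(self):
        with pytest.raises(ValueError, match="exceeds"):
            bs.hard_pulse(np.pi / 2, 1e-6, b1_max=1e-5)


class TestEPI:
    def test_sampling_geometry(self):
        seq = bs.epi_sequence(0.23, 100, 0.1)
        events = seq.adc_events()
        assert sum(ev.num_samples for _, _, ev in events) == 10_000
        ks = bs.k_trajectory(seq)
        dkx = np.abs(np.diff(ks[0][:2, 0]))[0]
        assert dkx == pytest.approx(1 / 0.23, rel=1e-9)
        kmax = max(np.max(np.abs(k[:, :2])) for k in ks)
        assert kmax == pytest.approx(100 / (2 * 0.23), rel=1e-2)

    def test_serpentine_order(self):
        ks = bs.k_trajectory(bs.epi_sequence(0.2, 16, 0.02))
        dirs = [np.sign(k[-1, 0] - k[0, 0]) for k in ks]
        assert dirs == [(-1.0) ** j for j in range(16)]
        lines = sorted(round(float(k[0, 1] * 0.2)) for k in ks)
        assert lines == list(range(-8, 8))  # every line exactly once

    def test_te_timing(self):
        te, n = 0.1, 100
        seq = bs.epi_sequence(0.23, n, te)
        _, t0, ev = seq.adc_events()[n // 2]
        t_center = t0 + ev.sample_times[n // 2]
        rf_center = seq.blocks[0].rf.raster / 2.0
        assert t_center - rf_center == pytest.approx(te, abs=2e-6)

    def test_te_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            bs.epi_sequence(0.23, 100, 0.01)

    def test_se_variant(self):
        te = 0.1
        seq = bs.epi_sequence(0.23, 100, te, variant="se")
        assert seq.definitions["refocus_times"]
        rfs = [b.rf for b in seq.blocks if b.rf is not None]
        assert len(rfs) == 2
        flip180 = abs(rfs[1].amplitude[0]) * GAMMA * rfs[1].duration
        assert flip180 == pytest.approx(np.pi)

    def test_respects_limits(self):
        bs.epi_sequence(0.23, 100, 0.1).validate(bs.Scanner())


class TestSpiral:
    def test_reaches_kmax(self):
        fov, n = 0.23, 100
        seq = bs.spiral_sequence(fov, n, 1e-4)
        k_end = np.linalg.norm(bs.k_trajectory(seq)[0][-1, :2])
        assert abs(k_end - n / (2 * fov)) <= 0.02 * n / (2 * fov)

    def test_interleaves_are_rotations(self):
        seq = bs.spiral_sequence(0.2, 32, 1e-4, interleaves=8)
        ks = bs.k_trajectory(seq)
        assert len(ks) == 8
        base = ks[0][:, :2]
        rot = 2 * np.pi / 8
        R = np.asarray([[np.cos(rot), -np.sin(rot)],
                        [np.sin(rot), np.cos(rot)]])
        assert np.allclose(ks[1][:, :2], base @ R.T, atol=1e-9)

    def test_adc_start_at_te(self):
        te = 1e-4
        seq = bs.spiral_sequence(0.2, 32, te)
        _, t0, ev = seq.adc_events()[0]
        rf_center = seq.blocks[0].rf.raster / 2.0
        assert t0 + ev.delay - rf_center == pytest.approx(te, abs=2e-6)

    def test_respects_limits(self):
        sc = bs.Scanner()
        seq = bs.spiral_sequence(0.23, 100, 1e-4, scanner=sc)
        for b in seq.blocks:
            for g in b.gradients():
                g.validate_limits(sc)


class TestMRFSchedule:
    def test_stated_ranges(self):
        s = bs.mrf_schedule(158, seed=3)
        assert np.all(s.flip_angles >= 0)
        assert np.all(s.flip_angles <= np.deg2rad(80) + 1e-12)
        assert np.all(s.TRs >= 14.5e-3) and np.all(s.TRs <= 18.0e-3)
        assert s.TE == 5e-3 and s.TI == 50e-3

    def test_uniform_spokes(self):
        s = bs.mrf_schedule(158, spoke_mode="uniform", seed=0)
        assert s.spoke_angles[1] == pytest.approx(np.pi / 158)

    def test_tiny_golden_angle_value(self):
        assert TINY_GOLDEN_ANGLE == pytest.approx(0.41238, abs=1e-5)
        s = bs.mrf_schedule(10, spoke_mode="tiny_golden", seed=0)
        assert s.spoke_angles[1] == pytest.approx(TINY_GOLDEN_ANGLE)

    def test_deterministic(self):
        a = bs.mrf_schedule(50, seed=9)
        b = bs.mrf_schedule(50, seed=9)
        assert np.array_equal(a.flip_angles, b.flip_angles)
        assert np.array_equal(a.TRs, b.TRs)

    @pytest.mark.parametrize("pattern", ["perlin", "sinusoid", "paper_mix"])
    def test_patterns(self, pattern):
        s = bs.mrf_schedule(40, pattern=pattern, seed=1)
        assert len(s.flip_angles) == 40

    def test_unknown_pattern(self):
        with pytest.raises(ValueError):
            bs.mrf_schedule(10, pattern="nope")

    def test_phase_cycling(self):
        s = bs.mrf_schedule(4, seed=0)
        assert s.rf_phases == pytest.approx([0.0, np.pi, 0.0, np.pi])


class TestMRFSequence:
    def test_balanced_and_echo_at_te(self):
        sched = bs.mrf_schedule(6, seed=2)
        seq = bs.mrf_bssfp_sequence(sched, 0.23, 100)
        ks = bs.k_trajectory(seq)
        dk = 1 / 0.23
        for (_, t0, ev), k in zip(seq.adc_events(), ks):
            assert np.linalg.norm(k[50, :2]) < 1e-6 * dk  # echo at k = 0
            assert np.linalg.norm(k[-1, :2]) <= dk * 50 + 1e-9
        starts = seq.block_starts
        # first excitation center sits TI after the inversion center
        inv_center = seq.blocks[0].rf.raster / 2.0
        exc_center = starts[2] + seq.blocks[2].rf.raster / 2.0
        assert exc_center - inv_center == pytest.approx(sched.TI, abs=2e-6)

    def test_te_timing(self):
        sched = bs.mrf_schedule(3, seed=0)
        seq = bs.mrf_bssfp_sequence(sched, 0.23, 100)
        starts = seq.block_starts
        rf_blocks = [i for i, b in enumerate(seq.blocks) if b.rf is not None]
        adc_list = seq.adc_events()
        for idx, (_, t0, ev) in zip(rf_blocks[1:], adc_list):
            rf_center = starts[idx] + seq.blocks[idx].rf.raster / 2.0
            t_echo = t0 + ev.sample_times[50]
            assert t_echo - rf_center == pytest.approx(sched.TE, abs=2e-6)

    def test_tr_durations(self):
        sched = bs.mrf_schedule(5, seed=1)
        seq = bs.mrf_bssfp_sequence(sched, 0.23, 100)
        # blocks: inv, TI delay, then (pulse, readout) pairs
        durs = [b.duration for b in seq.blocks[2:]]
        trs = [durs[2 * i] + durs[2 * i + 1] for i in range(5)]
        assert trs == pytest.approx(sched.TRs, abs=2e-6)
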