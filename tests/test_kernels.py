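import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blochsim as bs
from blochsim.core import DiscreteSequence, GAMMA, Mag
from blochsim.kernels import (
    apply_spinor,
    excitation_step,
    precession_block,
    relax,
    rotation_spinor,
    spinor_from_field,
)
from blochsim.oracle import rotate_rodrigues


def as_vec(m: Mag) -> np.ndarray:
    return np.column_stack([m.xy.real, m.xy.imag, m.z])


class TestSpinorFromField:
    def test_zero_field_is_identity(self):
        s = spinor_from_field(0.0, 0.0, 1e-3)
        assert s.alpha == 1.0 and s.beta == 0.0

    def test_90_about_x(self):
        # gamma*B1*dt = pi/2, B1 along +x: equilibrium tips to +y
        b1 = (np.pi / 2) / (GAMMA * 1e-3)
        m = apply_spinor(spinor_from_field(b1, 0.0, 1e-3), Mag([0j], [1.0]))
        assert m.xy[0] == pytest.approx(1j, abs=1e-12)
        assert m.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_z_rotation_phase_sign(self):
        # positive Bz: phase -gamma*Bz*dt on Mxy
        bz, dt = 1e-6, 1e-4
        m = apply_spinor(spinor_from_field(0.0, bz, dt), Mag([1.0 + 0j], [0.0]))
        assert m.xy[0] == pytest.approx(np.exp(-1j * GAMMA * bz * dt), abs=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            spinor_from_field(0.0, 0.0, -1.0)

    def test_rotation_spinor_matches_field_spinor(self):
        s1 = rotation_spinor(0.3, 0.7)
        b1 = 0.3 / (GAMMA * 1e-3) * np.exp(0.7j)
        s2 = spinor_from_field(b1, 0.0, 1e-3)
        assert s1.alpha == pytest.approx(s2.alpha, abs=1e-12)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)


class TestRelax:
    def test_closed_form(self):
        m = relax(Mag([1.0 + 0j], [0.0]), 0.05, 0.1, 0.02, 1.0)
        assert abs(m.xy[0]) == pytest.approx(np.exp(-0.05 / 0.02), abs=1e-14)
        assert m.z[0] == pytest.approx(1 - np.exp(-0.05 / 0.1), abs=1e-14)

    def test_infinite_times(self):
        m = relax(Mag([1.0 + 0j], [0.3]), 1.0, np.inf, np.inf, 1.0)
        assert m.xy[0] == 1.0 and m.z[0] == 0.3

    def test_zero_dt_identity(self):
        m = relax(Mag([0.5j], [0.2]), 0.0, 0.1, 0.1, 1.0)
        assert m.xy[0] == 0.5j and m.z[0] == pytest.approx(0.2)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    b1r=st.floats(-2e-5, 2e-5),
    b1i=st.floats(-2e-5, 2e-5),
    bz=st.floats(-1e-4, 1e-4),
    dt=st.floats(0.0, 1e-3),
    mx=st.floats(-1.0, 1.0),
    my=st.floats(-1.0, 1.0),
    mz=st.floats(-1.0, 1.0),
)
def test_spinor_agrees_with_rotation_matrix(b1r, b1i, bz, dt, mx, my, mz):
    s = spinor_from_field(b1r + 1j * b1i, bz, dt)
    assert abs(abs(s.alpha) ** 2 + abs(s.beta) ** 2 - 1.0) <= 1e-9
    m = apply_spinor(s, Mag([mx + 1j * my], [mz]))
    ref = rotate_rodrigues(
        np.asarray([[mx, my, mz]]), b1r, b1i, bz, dt, GAMMA
    )[0]
    assert np.max(np.abs(as_vec(m)[0] - ref)) <= 1e-12


class TestExcitationStep:
    def phantom(self):
        return bs.Phantom([0.01], [0.0], [0.0], [1.0], [np.inf], [np.inf],
                          [100.0])

    def test_b1_zero_reduces_to_phase(self):
        ph = self.phantom()
        m = excitation_step(Mag([1.0 + 0j], [0.0]), ph, 0.0,
                            (2e-3, 0.0, 0.0), 1e-4, 0.0)
        phase = -(GAMMA * 2e-3 * 0.01 + 100.0) * 1e-4
        assert m.xy[0] == pytest.approx(np.exp(1j * phase), abs=1e-12)

    def test_relaxation_applied(self):
        ph = bs.Phantom([0.0], [0.0], [0.0], [1.0], [0.1], [0.02], [0.0])
        m = excitation_step(Mag([1.0 + 0j], [0.0]), ph, 0.0,
                            (0.0, 0.0, 0.0), 1e-3, 0.0)
        assert abs(m.xy[0]) == pytest.approx(np.exp(-1e-3 / 0.02), abs=1e-12)


class TestPrecessionBlock:
    def dseq(self, t, gx, adc=None):
        n = len(t)
        adc = np.zeros(n, bool) if adc is None else np.asarray(adc)
        z = np.zeros(n)
        return DiscreteSequence(np.asarray(t, float), np.zeros(n, complex),
                                np.asarray(gx, float), z, z.copy(), adc)

    def test_rejects_rf(self):
        d = self.dseq([0.0, 1e-4], [0.0, 0.0])
        d.B1[0] = 1e-5
        ph = bs.Phantom([0.0], [0.0], [0.0], [1.0], [1.0], [0.1], [0.0])
        with pytest.raises(RuntimeError, match="regime"):
            precession_block(Mag([0j], [1.0]), ph, d)

    def test_constant_gradient_phase(self):
        G, x, dt = 5e-3, 0.02, 1e-3
        ph = bs.Phantom([x], [0.0], [0.0], [1.0], [np.inf], [np.inf], [0.0])
        m, _ = precession_block(Mag([1.0 + 0j], [0.0]), ph,
                                self.dseq([0.0, dt], [G, G]))
        assert m.xy[0] == pytest.approx(np.exp(-1j * GAMMA * G * x * dt),
                                        abs=1e-12)

    def test_samples_carry_t2_decay(self):
        ph = bs.Phantom([0.0], [0.0], [0.0], [1.0], [np.inf], [0.05], [0.0])
        t = np.asarray([0.0, 0.01, 0.02])
        d = self.dseq(t, np.zeros(3), adc=[False, True, True])
        _, samples = precession_block(Mag([1.0 + 0j], [0.0]), ph, d)
        assert samples == pytest.approx(np.exp(-t[1:] / 0.05), abs=1e-12)

    def test_motion_path_matches_static_for_zero_velocity(self):
        ph = bs.circles_phantom(spacing=20e-3)
        ph_m = bs.with_linear_motion(ph, 0.0)
        ph_m.motion = lambda x, y, z, t: (
            np.zeros_like(x), np.zeros_like(y), np.zeros_like(z)
        )
        t = np.linspace(0.0, 5e-3, 21)
        gx = np.linspace(0.0, 5e-3, 21)
        adc = np.zeros(21, bool)
        adc[5::5] = True
        d = self.dseq(t, gx, adc)
        m0 = Mag(np.ones(ph.n_spins, complex), np.zeros(ph.n_spins))
        ms, ss = precession_block(m0.copy(), ph, d)
        mm, sm = precession_block(m0.copy(), ph_m, d)
        assert np.max(np.abs(ms.xy - mm.xy)) < 1e-12
        assert np.max(np.abs(ss - sm)) < 1e-12 * max(np.abs(ss).max(), 1.0)

    def test_z_recovery_over_block(self):
        ph = bs.Phantom([0.0], [0.0], [0.0], [2.0], [0.1], [0.1], [0.0])
        m, _ = precession_block(Mag([0j], [0.0]), ph,
                                self.dseq([0.0, 0.1], [0.0, 0.0]))
        assert m.z[0] == pytest.approx(2.0 * (1 - np.exp(-1.0)), abs=1e-12)
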