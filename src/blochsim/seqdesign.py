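"""Pulse-sequence construction.

Builders for the validation sequences: hard-pulse excitation, single-shot
gradient-echo / spin-echo EPI, a slew-limited Archimedean spiral, and the
fingerprinting train (inversion-prepared radial bSSFP with pseudo-random
flip angles and TRs).

All event timings are kept on a 1 us raster so the sequences survive a
Pulseq round trip bit-faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ADCEvent,
    GAMMA,
    GradEvent,
    RFEvent,
    Scanner,
    SeqBlock,
    Sequence,
)

__all__ = [
    "MRFSchedule",
    "hard_pulse",
    "epi_sequence",
    "spiral_sequence",
    "mrf_schedule",
    "mrf_bssfp_sequence",
    "builtin_sequence",
]

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0
#: Tiny golden angle increment (rad): pi / (golden ratio + 6)
TINY_GOLDEN_ANGLE = np.pi / (GOLDEN_RATIO + 6.0)


def _round_us(t: float) -> float:
    return round(t * 1e6) / 1e6


def hard_pulse(
    flip: float,
    duration: float = 0.5e-3,
    phase: float = 0.0,
    gamma: float = GAMMA,
    b1_max: float | None = None,
) -> SeqBlock:
    """Block containing a constant-envelope (hard) RF pulse.

    The amplitude follows from ``flip = gamma * B1 * duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    amp = flip / (gamma * duration)
    if b1_max is not None and abs(amp) > b1_max:
        raise ValueError(
            f"required B1 {abs(amp):.3g} T exceeds limit {b1_max:.3g} T"
        )
    rf = RFEvent(np.asarray([amp], dtype=complex), raster=duration,
                 phase_offset=phase)
    return SeqBlock(duration=duration, rf=rf)


def _trap(axis: str, area: float, scanner: Scanner,
          rise: float = 1e-4, flat: float = 3e-4) -> GradEvent:
    """Symmetric trapezoid with the requested area (T*s/m)."""
    amp = area / (flat + rise)
    g = GradEvent(
        np.asarray([0.0, rise, rise + flat, 2 * rise + flat]),
        np.asarray([0.0, amp, amp, 0.0]),
        axis,
    )
    g.validate_limits(scanner)
    return g


def _delay_block(duration: float) -> SeqBlock:
    return SeqBlock(duration=_round_us(duration))


def epi_sequence(
    fov: float,
    n: int,
    te: float,
    variant: str = "gre",
    scanner: Scanner | None = None,
    dwell: float = 5e-6,
    ramp: float = 1e-4,
    blip_ramp: float = 5e-5,
    pulse_dur: float = 0.5e-3,
) -> Sequence:
    """Single-shot EPI: hard 90, pre-phasers, serpentine readout train.

    ``n`` readout lines of ``n`` samples cover k-space at
    ``dk = 1/fov`` out to ``kmax = n/(2*fov)`` per axis; line ``j``
    sits at ``ky = (j - n/2)*dk`` and even/odd lines alternate readout
    polarity.  Timing places the center sample of the center line at
    ``te`` after the excitation center.  ``variant='se'`` inserts a hard
    180 at ``te/2`` (recorded in ``definitions['refocus_times']`` for
    trajectory bookkeeping).
    """
    if variant not in ("gre", "se"):
        raise ValueError("variant must be 'gre' or 'se'")
    scanner = scanner or Scanner()
    c = scanner.gamma / (2.0 * np.pi)
    dk = 1.0 / fov
    kmax = n / (2.0 * fov)
    g_read = dk / (c * dwell)
    if g_read > scanner.Gmax or g_read / ramp > scanner.Smax:
        raise ValueError("readout gradient exceeds scanner limits")
    a_half = c * g_read * ramp / 2.0  # k gained on one readout ramp

    rf90 = hard_pulse(np.pi / 2.0, pulse_dur, gamma=scanner.gamma)

    pre = SeqBlock(
        duration=5e-4,
        gx=_trap("x", -(kmax + a_half) / c, scanner),
        gy=_trap("y", -kmax / c, scanner),
    )

    flat = (n - 1) * dwell
    line_dur = 2 * ramp + flat

    def line_block(j: int) -> SeqBlock:
        sign = 1.0 if j % 2 == 0 else -1.0
        g = GradEvent(
            np.asarray([0.0, ramp, ramp + flat, line_dur]),
            sign * np.asarray([0.0, g_read, g_read, 0.0]),
            "x",
        )
        adc = ADCEvent(num_samples=n, dwell=dwell, delay=ramp)
        return SeqBlock(duration=line_dur, gx=g, adc=adc)

    blip_amp = dk / (c * blip_ramp)
    blip = SeqBlock(
        duration=2 * blip_ramp,
        gy=GradEvent(
            np.asarray([0.0, blip_ramp, 2 * blip_ramp]),
            np.asarray([0.0, blip_amp, 0.0]),
            "y",
        ),
    )

    # time from train start to the center sample of the center line
    t_train_center = (n // 2) * (line_dur + 2 * blip_ramp) + ramp + (n // 2) * dwell
    echo_spacing = line_dur + 2 * blip_ramp

    blocks = [rf90]
    refocus_times = []
    if variant == "se":
        d1 = te / 2.0 - pulse_dur
        if d1 < 0:
            raise ValueError("te too short for the spin-echo refocusing pulse")
        rf180 = hard_pulse(np.pi, pulse_dur, phase=np.pi / 2.0,
                           gamma=scanner.gamma)
        blocks += [_delay_block(d1), rf180]
        refocus_times.append(te / 2.0 + pulse_dur / 2.0)
    t_so_far = sum(b.duration for b in blocks) + pre.duration
    delay = te + pulse_dur / 2.0 - (t_so_far + t_train_center)
    if delay < -1e-9:
        raise ValueError(
            f"te={te} too short for the readout train "
            f"(needs >= {t_so_far + t_train_center - pulse_dur / 2.0:.4g} s)"
        )
    blocks += [_delay_block(max(delay, 0.0)), pre]
    for j in range(n):
        blocks.append(line_block(j))
        if j < n - 1:
            blocks.append(blip)

    seq = Sequence(
        blocks,
        definitions={
            "name": f"{variant}_epi",
            "fov": fov,
            "matrix": n,
            "te": te,
            "echo_spacing": echo_spacing,
            "trajectory": "cartesian_epi",
        },
    )
    if refocus_times:
        seq.definitions["refocus_times"] = refocus_times
    return seq


def _archimedean_waveform(
    kmax: float, turns: float, scanner: Scanner, points_per_turn: int = 40
):
    """Greedy slew-limited time parameterization of an Archimedean spiral.

    Returns vertex times (s, on a 1 us raster), (M, 2) gradient vertex
    amplitudes (T/m), and the time at which the spiral reaches ``kmax``
    (before the final ramp-down to zero gradient).  Because the waveform
    is piecewise *linear* between vertices, each vertex is chosen so that
    the trapezoid area over the segment equals the required k increment
    exactly: ``g_next = 2*dk/(c*dt) - g_prev``.
    """
    c = scanner.gamma / (2.0 * np.pi)
    g_lim, s_lim = 0.9 * scanner.Gmax, 0.9 * scanner.Smax
    m = max(int(np.ceil(turns * points_per_turn)), 8)
    tau = np.linspace(0.0, 1.0, m + 1)
    k = kmax * tau * np.exp(2j * np.pi * turns * tau)
    dk = np.column_stack([np.diff(k.real), np.diff(k.imag)])

    times = [0.0]
    grads = [np.zeros(2)]
    for i in range(m):
        u = dk[i] / c  # required gradient-time area (T/m * s)
        g_prev = grads[-1]
        dt = np.ceil(max(np.linalg.norm(u) / g_lim, 1e-6) * 1e6 - 1e-9) / 1e6
        while True:
            g_next = 2.0 * u / dt - g_prev
            if (
                np.linalg.norm(g_next) <= g_lim
                and np.linalg.norm(g_next - g_prev) / dt <= s_lim
            ):
                break
            dt += 1e-6
        grads.append(g_next)
        times.append(times[-1] + dt)
    t_spiral = times[-1]
    # ramp down to zero gradient (adds a small k drift, rewound later)
    g_end = np.linalg.norm(grads[-1])
    if g_end > 0:
        dt = np.ceil(g_end / s_lim * 1e6) / 1e6
        times.append(times[-1] + dt)
        grads.append(np.zeros(2))
    return np.asarray(times), np.asarray(grads), t_spiral


def spiral_sequence(
    fov: float,
    n: int,
    te: float,
    interleaves: int = 1,
    scanner: Scanner | None = None,
    pulse_dur: float = 1e-4,
) -> Sequence:
    """Interleaved Archimedean spiral-out acquisition with hard pulses.

    Each interleave excites with a hard 90 and reads a spiral reaching
    ``kmax = n/(2*fov)`` with ``n/(2*interleaves)`` turns, respecting the
    scanner gradient and slew limits; interleave ``l`` is the base spiral
    rotated by ``2*pi*l/interleaves``.  The ADC spans the whole readout,
    starting ``te`` after the excitation center.
    """
    scanner = scanner or Scanner()
    kmax = n / (2.0 * fov)
    turns = n / (2.0 * interleaves)
    d0 = te - pulse_dur / 2.0
    if d0 < 0:
        raise ValueError("te shorter than half the excitation pulse")
    d0 = _round_us(d0)
    t_wave, g_wave, t_spiral = _archimedean_waveform(kmax, turns, scanner)
    # ADC covers the spiral proper at the 1 us raster, so its last sample
    # sits exactly at |k| = kmax
    dwell = 1e-6
    n_adc = int(round(t_spiral * 1e6)) + 1
    block_dur = _round_us(d0 + t_wave[-1])
    # net gradient-time area of one interleave, rewound after the readout
    # so every shot starts from k = 0
    area = np.sum(
        0.5 * (g_wave[:-1] + g_wave[1:]) * np.diff(t_wave)[:, None], axis=0
    )

    blocks = []
    for l in range(interleaves):
        rot = 2.0 * np.pi * l / interleaves
        R = np.asarray(
            [[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]]
        )
        g_rot = g_wave @ R.T
        a_rot = R @ area
        blocks.append(hard_pulse(np.pi / 2.0, pulse_dur, gamma=scanner.gamma))
        blocks.append(
            SeqBlock(
                duration=block_dur,
                gx=GradEvent(d0 + t_wave, g_rot[:, 0], "x"),
                gy=GradEvent(d0 + t_wave, g_rot[:, 1], "y"),
                adc=ADCEvent(num_samples=n_adc, dwell=dwell, delay=d0),
            )
        )
        blocks.append(
            SeqBlock(
                duration=5e-4,
                gx=_trap("x", -a_rot[0], scanner),
                gy=_trap("y", -a_rot[1], scanner),
            )
        )
    seq = Sequence(
        blocks,
        definitions={
            "name": "spiral",
            "fov": fov,
            "matrix": n,
            "te": te,
            "interleaves": interleaves,
            "trajectory": "spiral",
        },
    )
    seq.validate(scanner)
    return seq


@dataclass
class MRFSchedule:
    """Per-TR acquisition parameters for a fingerprinting train."""

    flip_angles: np.ndarray  # rad, within [0, 80 deg]
    TRs: np.ndarray  # s
    TE: float  # s
    TI: float  # s
    spoke_angles: np.ndarray  # rad, in [0, pi)

    def __post_init__(self) -> None:
        self.flip_angles = np.asarray(self.flip_angles, dtype=float)
        self.TRs = np.asarray(self.TRs, dtype=float)
        self.spoke_angles = np.asarray(self.spoke_angles, dtype=float)
        if not (
            len(self.flip_angles) == len(self.TRs) == len(self.spoke_angles)
        ):
            raise ValueError("schedule arrays must have equal length")
        if np.any(self.TRs < self.TE):
            raise ValueError("every TR must exceed TE")

    @property
    def n_tr(self) -> int:
        return len(self.TRs)

    @property
    def rf_phases(self) -> np.ndarray:
        """Alternating 0/pi excitation phases (bSSFP phase cycling)."""
        return np.pi * (np.arange(self.n_tr) % 2)


def _gradient_noise_1d(n: int, rng: np.random.Generator, octaves: int = 4):
    """Seeded 1-D gradient ('Perlin-style') noise on n points in [0, 1]."""
    out = np.zeros(n)
    t = np.arange(n) / n
    for o in range(octaves):
        cells = 4 * 2**o
        g = rng.uniform(-1.0, 1.0, cells + 1)
        pos = t * cells
        i0 = np.floor(pos).astype(int)
        f = pos - i0
        fade = f * f * f * (f * (f * 6 - 15) + 10)
        v0 = g[i0] * f
        v1 = g[i0 + 1] * (f - 1.0)
        out += (v0 + fade * (v1 - v0)) * 0.5**o
    out -= out.min()
    ptp = np.ptp(out)
    return out / ptp if ptp > 0 else out


def mrf_schedule(
    n_tr: int,
    pattern: str = "perlin",
    spoke_mode: str = "uniform",
    seed: int = 0,
    n_spokes: int | None = None,
) -> MRFSchedule:
    """Pseudo-random fingerprinting schedule.

    Flip angles lie in [0, 80 deg] following a smooth seeded pattern
    (``perlin``), a noisy sinusoid (``sinusoid``), or the half-and-half
    mix of the two (``paper_mix``).  TRs are uniform in [14.5, 18] ms,
    TE = 5 ms, TI = 50 ms.  Spokes advance by ``pi/n_spokes`` (uniform)
    or by the tiny golden angle ``pi/(golden_ratio + 6)``.
    """
    if n_tr < 1:
        raise ValueError("n_tr must be >= 1")
    rng = np.random.default_rng(seed)
    flip_max = np.deg2rad(80.0)

    def perlin(n):
        return flip_max * _gradient_noise_1d(n, rng)

    def sinusoid(n):
        lobe = 250 if n >= 500 else max(n // 2, 1)
        base = np.abs(np.sin(np.pi * np.arange(n) / lobe))
        noisy = base + rng.normal(0.0, 0.05, n)
        return flip_max * np.clip(noisy, 0.0, 1.0)

    if pattern == "perlin":
        flips = perlin(n_tr)
    elif pattern == "sinusoid":
        flips = sinusoid(n_tr)
    elif pattern == "paper_mix":
        n1 = n_tr // 2
        flips = np.concatenate([perlin(n1), sinusoid(n_tr - n1)])
    else:
        raise ValueError(f"unknown flip pattern {pattern!r}")

    trs = np.round(rng.uniform(14.5e-3, 18.0e-3, n_tr), 6)
    if spoke_mode == "uniform":
        dtheta = np.pi / (n_spokes if n_spokes is not None else n_tr)
    elif spoke_mode == "tiny_golden":
        dtheta = TINY_GOLDEN_ANGLE
    else:
        raise ValueError(f"unknown spoke mode {spoke_mode!r}")
    spokes = (np.arange(n_tr) * dtheta) % np.pi
    return MRFSchedule(flips, trs, TE=5e-3, TI=50e-3, spoke_angles=spokes)


def mrf_bssfp_sequence(
    schedule: MRFSchedule,
    fov: float,
    n: int,
    scanner: Scanner | None = None,
    pulse_dur: float = 1e-4,
    dwell: float = 1e-5,
    ramp: float = 5e-5,
) -> Sequence:
    """Inversion-prepared radial bSSFP fingerprinting acquisition.

    A hard 180 inversion, a TI delay, then one excitation + balanced
    radial readout per TR: the spoke at the scheduled angle crosses
    k = 0 at TE after the pulse center, and the gradient first moment is
    refunded to zero within every TR (the bSSFP condition).  RF phases
    alternate 0/pi; the ADC demodulates with the same phase.
    """
    scanner = scanner or Scanner()
    c = scanner.gamma / (2.0 * np.pi)
    dk = 1.0 / fov
    g_read = dk / (c * dwell)
    if g_read > scanner.Gmax or g_read / ramp > scanner.Smax:
        raise ValueError("readout gradient exceeds scanner limits")

    flat = (n - 1) * dwell
    f_pre = (n / 2) * dwell - ramp / 2.0
    f_rw = (n / 2 - 1) * dwell - ramp / 2.0
    if f_pre <= 0 or f_rw <= 0:
        raise ValueError("readout too short for balanced pre/rewind lobes")
    # spoke profile along the readout direction: prephase, readout, rewind
    t_v = []
    a_v = []
    t0 = 0.0
    for amp, fl in ((-g_read, f_pre), (g_read, flat), (-g_read, f_rw)):
        # consecutive lobes share their zero-crossing vertex
        if not t_v:
            t_v.append(t0)
            a_v.append(0.0)
        t_v += [t0 + ramp, t0 + ramp + fl, t0 + 2 * ramp + fl]
        a_v += [amp, amp, 0.0]
        t0 += 2 * ramp + fl
    t_v = np.asarray(t_v)
    a_v = np.asarray(a_v)
    lobes_dur = t0
    t_before_echo = (2 * ramp + f_pre) + ramp + (n / 2) * dwell

    inv = hard_pulse(np.pi, pulse_dur, gamma=scanner.gamma)
    ti_delay = schedule.TI - pulse_dur
    if ti_delay < 0:
        raise ValueError("TI shorter than the inversion pulse")
    blocks = [inv, _delay_block(ti_delay)]
    phases = schedule.rf_phases
    for k in range(schedule.n_tr):
        tr = schedule.TRs[k]
        d1 = schedule.TE - pulse_dur / 2.0 - t_before_echo
        if d1 < 0:
            raise ValueError("TE incompatible with the readout duration")
        d1 = _round_us(d1)
        ro_dur = _round_us(tr - pulse_dur)
        if d1 + lobes_dur > ro_dur + 1e-9:
            raise ValueError("TR too short for the balanced readout")
        blocks.append(
            hard_pulse(
                schedule.flip_angles[k], pulse_dur, phase=phases[k],
                gamma=scanner.gamma,
            )
        )
        ca, sa = np.cos(schedule.spoke_angles[k]), np.sin(schedule.spoke_angles[k])
        grads = {}
        if abs(ca) > 1e-12:
            grads["gx"] = GradEvent(d1 + t_v, ca * a_v, "x")
        if abs(sa) > 1e-12:
            grads["gy"] = GradEvent(d1 + t_v, sa * a_v, "y")
        adc = ADCEvent(
            num_samples=n, dwell=dwell,
            delay=d1 + (2 * ramp + f_pre) + ramp, phase=phases[k],
        )
        blocks.append(SeqBlock(duration=ro_dur, adc=adc, **grads))
    seq = Sequence(
        blocks,
        definitions={
            "name": "mrf_bssfp",
            "fov": fov,
            "matrix": n,
            "te": schedule.TE,
            "ti": schedule.TI,
            "trajectory": "radial",
            "spoke_angles": [float(a) for a in schedule.spoke_angles],
        },
    )
    seq.validate(scanner)
    return seq


def builtin_sequence(name: str, fov: float, n: int, te: float,
                     scanner: Scanner | None = None, seed: int = 0) -> Sequence:
    """Look up a sequence builder by name (used by the CLI)."""
    if name == "epi":
        return epi_sequence(fov, n, te, "gre", scanner)
    if name == "se-epi":
        return epi_sequence(fov, n, te, "se", scanner)
    if name == "spiral":
        return spiral_sequence(fov, n, te, scanner=scanner)
    if name == "mrf":
        sched = mrf_schedule(158, seed=seed)
        return mrf_bssfp_sequence(sched, fov, n, scanner)
    raise KeyError(f"unknown builtin sequence {name!r}")
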