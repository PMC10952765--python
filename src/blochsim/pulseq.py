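"""Pulseq .seq text-format reader and writer (v1.4 subset).

Supports the sections [VERSION], [DEFINITIONS], [BLOCKS], [RF],
[GRADIENTS], [TRAP], [ADC] and [SHAPES]; v1.2/1.3 files are accepted by
mapping the legacy delay-column block layout.  Unsupported sections
([EXTENSIONS], ...) are skipped with a warning.

Pulseq stores RF amplitudes in Hz and gradients in Hz/m; conversion to
T and T/m divides by gamma/2pi, so the gyromagnetic ratio is an explicit
argument.  Arbitrary-gradient shape samples are vertex values connected
linearly, consistent with the solver's piecewise-linear assumption.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    ADCEvent,
    GAMMA,
    GradEvent,
    RFEvent,
    SeqBlock,
    Sequence,
)

__all__ = ["read_pulseq", "write_pulseq", "compress_shape", "decompress_shape"]

_RF_RASTER = 1e-6
_GRAD_RASTER = 1e-6
_BLOCK_RASTER = 1e-6
_ADC_RASTER = 1e-7


# ---------------------------------------------------------------------------
# Shape codec


#: Quantization step applied before differencing: run detection requires
#: exactly repeating derivatives, which float noise would otherwise break
#: (shapes are unit-normalized, so 1e-9 is far below any physical scale).
SHAPE_QUANTUM = 1e-9


def compress_shape(samples: np.ndarray) -> np.ndarray:
    """Run-length encode the derivative of a shape.

    The stream holds first differences; a value appearing twice in a row
    is followed by the count of *additional* repeats (so ``v v k`` means
    k+2 copies of v).  Samples are quantized to :data:`SHAPE_QUANTUM`
    first so that, e.g., a linear ramp of 100 steps of 0.01 compresses to
    the three entries ``[0.01, 0.01, 98]``.
    """
    q = np.round(np.asarray(samples, dtype=float) / SHAPE_QUANTUM)
    deriv = np.concatenate([q[:1], np.diff(q)]) * SHAPE_QUANTUM
    out: list = []
    i = 0
    n = len(deriv)
    while i < n:
        j = i
        while j + 1 < n and deriv[j + 1] == deriv[i]:
            j += 1
        run = j - i + 1
        if run >= 2:
            out += [deriv[i], deriv[i], float(run - 2)]
        else:
            out.append(deriv[i])
        i = j + 1
    return np.asarray(out)


def decompress_shape(stream, num_samples: int) -> np.ndarray:
    """Invert :func:`compress_shape`.

    Expands the run-length-encoded derivative stream and cumulative-sums
    it; raises if the expanded length disagrees with ``num_samples``.
    """
    stream = np.asarray(stream, dtype=float)
    deriv: list = []
    i = 0
    n = len(stream)
    while i < n:
        v = stream[i]
        if i + 1 < n and stream[i + 1] == v:
            count = int(round(stream[i + 2])) if i + 2 < n else 0
            if count < 0:
                raise ValueError("corrupt shape: negative repeat count")
            deriv.extend([v] * (2 + count))
            i += 3
        else:
            deriv.append(v)
            i += 1
    if len(deriv) != num_samples:
        raise ValueError(
            f"corrupt shape: expanded to {len(deriv)} samples, "
            f"expected {num_samples}"
        )
    return np.cumsum(np.asarray(deriv))


# ---------------------------------------------------------------------------
# Writer


class _Registry:
    """Deduplicating id assignment for events and shapes."""

    def __init__(self):
        self.by_key = {}
        self.rows = []

    def add(self, key, payload):
        if key not in self.by_key:
            self.by_key[key] = len(self.rows) + 1
            self.rows.append(payload)
        return self.by_key[key]


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_pulseq(seq: Sequence, path, gamma: float = GAMMA) -> None:
    """Write a v1.4 .seq file for the supported event subset.

    All event timings must sit on a 1 us raster; RF envelopes are
    expanded onto the RF raster before encoding.
    """
    c = gamma / (2.0 * np.pi)
    shapes = _Registry()
    rfs = _Registry()
    traps = _Registry()
    grads = _Registry()
    adcs = _Registry()
    block_rows = []

    def shape_id(samples: np.ndarray) -> int:
        samples = np.asarray(samples, dtype=float)
        key = (len(samples), samples.round(9).tobytes())
        comp = compress_shape(samples)
        data = samples if len(comp) >= len(samples) else comp
        return shapes.add(key, (len(samples), data))

    def us(t: float, what: str) -> int:
        v = t * 1e6
        if abs(v - round(v)) > 1e-3:
            raise ValueError(f"{what} ({t:.9g} s) is not on the 1 us raster")
        return int(round(v))

    for b in seq.blocks:
        rf_id = gx_id = gy_id = gz_id = adc_id = 0
        if b.rf is not None:
            rf = b.rf
            nsub = us(rf.raster, "RF raster")
            env = np.repeat(rf.amplitude, nsub)
            peak = np.max(np.abs(env))
            mag = np.abs(env) / peak if peak > 0 else np.abs(env)
            ph = np.mod(np.angle(env) / (2 * np.pi), 1.0)
            ph[mag == 0] = 0.0
            m_id = shape_id(mag)
            p_id = shape_id(ph)
            rf_id = rfs.add(
                (m_id, p_id, round(peak * c, 9), us(rf.delay, "RF delay"),
                 round(rf.freq_offset, 9), round(rf.phase_offset, 12)),
                f"{_fmt(peak * c)} {m_id} {p_id} 0 "
                f"{us(rf.delay, 'RF delay')} "
                f"{_fmt(rf.freq_offset / (2 * np.pi))} "
                f"{_fmt(rf.phase_offset)}",
            )
        for g in b.gradients():
            t = g.times
            a = g.amplitudes
            is_trap = (
                len(t) == 4 and a[0] == 0.0 and a[3] == 0.0 and a[1] == a[2]
            )
            is_tri = len(t) == 3 and a[0] == 0.0 and a[2] == 0.0
            if is_trap or is_tri:
                rise = us(t[1] - t[0], "trap rise")
                flat = 0 if is_tri else us(t[2] - t[1], "trap flat")
                fall = us(t[-1] - t[-2], "trap fall")
                delay = us(t[0], "trap delay")
                eid = traps.add(
                    (round(a[1] * c, 6), rise, flat, fall, delay),
                    f"{_fmt(a[1] * c)} {rise} {flat} {fall} {delay}",
                )
            else:
                peak = np.max(np.abs(a))
                norm = a / peak if peak > 0 else a
                s_id = shape_id(norm)
                t_id = shape_id((t - t[0]) / _GRAD_RASTER)
                delay = us(t[0], "gradient delay")
                eid = grads.add(
                    (s_id, t_id, round(peak * c, 6), delay),
                    f"{_fmt(peak * c)} {s_id} {t_id} {delay}",
                )
                eid = -eid  # mark as arbitrary gradient
            if g.axis == "x":
                gx_id = eid
            elif g.axis == "y":
                gy_id = eid
            else:
                gz_id = eid
        if b.adc is not None:
            adc = b.adc
            dwell_ns = adc.dwell * 1e9
            if abs(dwell_ns - round(dwell_ns)) > 1e-3:
                raise ValueError("ADC dwell is not an integer nanosecond count")
            adc_id = adcs.add(
                (adc.num_samples, int(round(dwell_ns)),
                 us(adc.delay, "ADC delay"), round(adc.phase, 12)),
                f"{adc.num_samples} {int(round(dwell_ns))} "
                f"{us(adc.delay, 'ADC delay')} 0 {_fmt(adc.phase)}",
            )
        block_rows.append(
            (us(b.duration, "block duration"), rf_id, gx_id, gy_id, gz_id, adc_id)
        )

    lines = ["# Pulseq sequence file", "[VERSION]", "major 1", "minor 4",
             "revision 0", ""]
    lines.append("[DEFINITIONS]")
    lines.append(f"BlockDurationRaster {_BLOCK_RASTER:g}")
    lines.append(f"RadiofrequencyRasterTime {_RF_RASTER:g}")
    lines.append(f"GradientRasterTime {_GRAD_RASTER:g}")
    lines.append(f"AdcRasterTime {_ADC_RASTER:g}")
    if "name" in seq.definitions:
        lines.append(f"Name {seq.definitions['name']}")
    if "fov" in seq.definitions:
        fov = seq.definitions["fov"]
        lines.append(f"FOV {_fmt(fov)} {_fmt(fov)} {_fmt(fov)}")
    lines.append("")
    lines.append("[BLOCKS]")
    for i, row in enumerate(block_rows):
        dur, rf_id, gx_id, gy_id, gz_id, adc_id = row

        def gcol(v):
            return str(v) if v >= 0 else f"a{-v}"

        lines.append(
            f"{i + 1} {dur} {rf_id} {gcol(gx_id)} {gcol(gy_id)} "
            f"{gcol(gz_id)} {adc_id} 0"
        )
    lines.append("")
    if rfs.rows:
        lines.append("[RF]")
        for i, row in enumerate(rfs.rows):
            lines.append(f"{i + 1} {row}")
        lines.append("")
    if grads.rows:
        lines.append("[GRADIENTS]")
        for i, row in enumerate(grads.rows):
            lines.append(f"{i + 1} {row}")
        lines.append("")
    if traps.rows:
        lines.append("[TRAP]")
        for i, row in enumerate(traps.rows):
            lines.append(f"{i + 1} {row}")
        lines.append("")
    if adcs.rows:
        lines.append("[ADC]")
        for i, row in enumerate(adcs.rows):
            lines.append(f"{i + 1} {row}")
        lines.append("")
    if shapes.rows:
        lines.append("[SHAPES]")
        for i, (num, data) in enumerate(shapes.rows):
            lines.append("")
            lines.append(f"shape_id {i + 1}")
            lines.append(f"num_samples {num}")
            # shortest round-trip formatting: the RLE decoder detects
            # runs by exact equality of the parsed values, so the text
            # must reproduce the binary stream bit-for-bit
            lines.extend(repr(float(v)) for v in data)
        lines.append("")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reader


def _split_sections(text: str) -> dict:
    sections: dict = {}
    current = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].upper()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def _parse_shapes(lines) -> dict:
    shapes = {}
    sid = None
    num = None
    data: list = []

    def flush():
        if sid is None:
            return
        arr = np.asarray(data, dtype=float)
        if len(arr) == num:
            samples = arr  # stored uncompressed
        else:
            samples = decompress_shape(arr, num)
        shapes[sid] = samples

    for line in lines:
        low = line.lower()
        if low.startswith("shape_id"):
            flush()
            sid = int(line.split()[1])
            num = None
            data = []
        elif low.startswith("num_samples"):
            num = int(line.split()[1])
        else:
            data.extend(float(v) for v in line.split())
    flush()
    return shapes


def read_pulseq(path, gamma: float = GAMMA) -> Sequence:
    """Parse a Pulseq .seq file (v1.2 to v1.4 subset) into a Sequence."""
    with open(path) as f:
        text = f.read()
    sections = _split_sections(text)

    known = {"VERSION", "DEFINITIONS", "BLOCKS", "RF", "GRADIENTS", "TRAP",
             "ADC", "SHAPES", "DELAYS", "SIGNATURE"}
    for name in sections:
        if name not in known:
            warnings.warn(f"skipping unsupported Pulseq section [{name}]")

    if "VERSION" not in sections:
        raise ValueError("Pulseq parse error: missing [VERSION] section")
    version = {}
    for line in sections["VERSION"]:
        k, v = line.split()[:2]
        version[k.lower()] = int(v)
    major, minor = version.get("major", 1), version.get("minor", 4)
    if (major, minor) > (1, 4):
        raise ValueError(f"unsupported Pulseq version {major}.{minor}")
    legacy = (major, minor) < (1, 4)

    defs: dict = {}
    for line in sections.get("DEFINITIONS", []):
        parts = line.split()
        defs[parts[0]] = parts[1:] if len(parts) > 2 else parts[1]
    rf_raster = float(defs.get("RadiofrequencyRasterTime", _RF_RASTER))
    grad_raster = float(defs.get("GradientRasterTime", _GRAD_RASTER))
    block_raster = float(defs.get("BlockDurationRaster", _BLOCK_RASTER))

    if "BLOCKS" not in sections:
        raise ValueError("Pulseq parse error: missing [BLOCKS] section")

    shapes = _parse_shapes(sections.get("SHAPES", []))
    c = gamma / (2.0 * np.pi)

    rf_events = {}
    for line in sections.get("RF", []):
        p = line.split()
        if legacy:
            eid, amp, m_id, p_id, delay, freq, phase = (
                int(p[0]), float(p[1]), int(p[2]), int(p[3]),
                float(p[4]), float(p[5]), float(p[6]),
            )
            t_id = 0
        else:
            eid, amp, m_id, p_id, t_id = (
                int(p[0]), float(p[1]), int(p[2]), int(p[3]), int(p[4]),
            )
            delay, freq, phase = float(p[5]), float(p[6]), float(p[7])
        if t_id != 0:
            raise ValueError("RF time shapes are not supported")
        mag = shapes[m_id]
        ph = shapes[p_id] if p_id != 0 else np.zeros_like(mag)
        env = (amp / c) * mag * np.exp(2j * np.pi * ph)
        rf_events[eid] = RFEvent(
            env, raster=rf_raster, delay=delay * 1e-6,
            freq_offset=2 * np.pi * freq, phase_offset=phase,
        )

    trap_events = {}
    for line in sections.get("TRAP", []):
        p = line.split()
        eid = int(p[0])
        amp = float(p[1]) / c
        rise, flat, fall, delay = (float(v) * 1e-6 for v in p[2:6])
        if rise <= 0 or fall <= 0:
            raise ValueError("trapezoids need nonzero ramps")
        times = [delay, delay + rise]
        amps = [0.0, amp]
        if flat > 0:
            times.append(delay + rise + flat)
            amps.append(amp)
        times.append(delay + rise + flat + fall)
        amps.append(0.0)
        trap_events[eid] = (np.asarray(times), np.asarray(amps))

    grad_events = {}
    for line in sections.get("GRADIENTS", []):
        p = line.split()
        eid = int(p[0])
        amp = float(p[1]) / c
        s_id = int(p[2])
        if legacy:
            t_id, delay = 0, float(p[3]) * 1e-6
        else:
            t_id, delay = int(p[3]), float(p[4]) * 1e-6
        vals = amp * shapes[s_id]
        if t_id != 0:
            times = delay + shapes[t_id] * grad_raster
        else:
            times = delay + np.arange(len(vals)) * grad_raster
        grad_events[eid] = (times, vals)

    adc_events = {}
    for line in sections.get("ADC", []):
        p = line.split()
        adc_events[int(p[0])] = ADCEvent(
            num_samples=int(p[1]), dwell=float(p[2]) * 1e-9,
            delay=float(p[3]) * 1e-6, phase=float(p[5]) if len(p) > 5 else 0.0,
        )

    delays = {}
    for line in sections.get("DELAYS", []):
        p = line.split()
        delays[int(p[0])] = float(p[1]) * 1e-6

    blocks = []
    for line in sections["BLOCKS"]:
        p = line.split()

        def gev(tok: str, axis: str):
            if tok.startswith("a"):
                times, vals = grad_events[int(tok[1:])]
                return GradEvent(times, vals, axis)
            gid = int(tok)
            if gid == 0:
                return None
            if gid in trap_events:
                times, vals = trap_events[gid]
            else:
                times, vals = grad_events[gid]
            return GradEvent(times, vals, axis)

        if legacy:
            delay_id = int(p[1])
            dur = None
        else:
            dur = int(p[1]) * block_raster
        rf = rf_events.get(int(p[2])) if int(p[2]) else None
        gx = gev(p[3], "x")
        gy = gev(p[4], "y")
        gz = gev(p[5], "z")
        adc = adc_events.get(int(p[6])) if int(p[6]) else None
        if dur is None:
            ends = [ev.end for ev in (rf, gx, gy, gz, adc) if ev is not None]
            dur = max(ends + [delays.get(delay_id, 0.0)])
        blocks.append(
            SeqBlock(duration=dur, rf=rf, gx=gx, gy=gy, gz=gz, adc=adc)
        )

    definitions = {}
    if "Name" in defs:
        definitions["name"] = (
            defs["Name"] if isinstance(defs["Name"], str) else defs["Name"][0]
        )
    if "FOV" in defs:
        fov = defs["FOV"]
        definitions["fov"] = float(fov[0] if isinstance(fov, list) else fov)
    return Sequence(blocks, definitions=definitions)
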