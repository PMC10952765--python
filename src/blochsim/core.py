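"""Domain types and unit conventions shared across the simulator.

All quantities are strict SI internally: seconds, meters, Tesla, T/m,
rad/s.  Literature values quoted in ms or mT/m are converted at
construction time by the callers.  The default gyromagnetic ratio is
``2*pi*42.58e6`` rad/s/T for protons, overridable per :class:`Scanner`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence as TSequence

import h5py
import numpy as np
import yaml

__all__ = [
    "GAMMA",
    "Scanner",
    "Phantom",
    "RFEvent",
    "GradEvent",
    "ADCEvent",
    "SeqBlock",
    "Sequence",
    "DiscreteSequence",
    "Mag",
    "Spinor",
    "SimConfig",
    "Readout",
    "RawData",
    "gamma_scaled",
    "equilibrium_mag",
    "spin_position",
    "write_phantom",
    "read_phantom",
    "read_scanner",
    "write_scanner",
]

#: Default proton gyromagnetic ratio (rad/s/T).
GAMMA = 2.0 * np.pi * 42.58e6

#: Tolerance used when merging nearly coincident time nodes (s).
TIME_MERGE_TOL = 1e-12


def gamma_scaled(gamma: float) -> float:
    """Express a gyromagnetic ratio in rad/us per mT.

    This is the factor by which a gradient amplitude given in mT/m must be
    multiplied to obtain the per-meter precession rate in rad/us — the
    scaling some simulators expect for gradient strengths.

    Parameters
    ----------
    gamma : float
        Gyromagnetic ratio in rad/s/T. Must be positive.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return gamma * 1e-9


@dataclass
class Scanner:
    """Hardware description: main field, gradient and slew limits.

    Attributes
    ----------
    B0 : main field (T)
    Gmax : maximum gradient amplitude (T/m)
    Smax : maximum slew rate (T/m/s)
    raster_time : minimum event time raster (s)
    gamma : gyromagnetic ratio (rad/s/T)
    """

    B0: float = 1.5
    Gmax: float = 60e-3
    Smax: float = 500.0
    raster_time: float = 1e-6
    gamma: float = GAMMA

    def __post_init__(self) -> None:
        for name in ("Gmax", "Smax", "raster_time", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Scanner.{name} must be positive")


# displacement(x0, y0, z0, t) -> (ux, uy, uz), Lagrangian convention
MotionField = Callable[[np.ndarray, np.ndarray, np.ndarray, float], tuple]


@dataclass
class Phantom:
    """Collection of isochromats with per-spin properties.

    ``x``/``y``/``z`` are positions at t=0 (m); ``M0`` is the proton
    density (a.u.); ``T1``/``T2`` relaxation times (s, np.inf allowed);
    ``dw`` is the off-resonance in rad/s.  ``motion``, if present, is a
    Lagrangian displacement field: a callable of the initial positions and
    time returning the displacement vector components (m).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    M0: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    dw: np.ndarray
    motion: Optional[MotionField] = None
    name: str = "phantom"

    def __post_init__(self) -> None:
        arrays = {}
        for f in ("x", "y", "z", "M0", "T1", "T2", "dw"):
            arrays[f] = np.atleast_1d(np.asarray(getattr(self, f), dtype=float))
            setattr(self, f, arrays[f])
        n = len(self.x)
        if n < 1:
            raise ValueError("Phantom must contain at least one spin")
        for f, arr in arrays.items():
            if len(arr) != n:
                raise ValueError(
                    f"Phantom.{f} has length {len(arr)}, expected {n}"
                )
        if np.any(self.M0 < 0):
            raise ValueError("M0 must be non-negative")
        if np.any(self.T1 <= 0) or np.any(self.T2 <= 0):
            raise ValueError("T1 and T2 must be positive")

    @property
    def n_spins(self) -> int:
        return len(self.x)

    def subset(self, idx: np.ndarray) -> "Phantom":
        """Phantom restricted to the given spin indices (shares motion)."""
        return Phantom(
            self.x[idx], self.y[idx], self.z[idx], self.M0[idx],
            self.T1[idx], self.T2[idx], self.dw[idx],
            motion=self.motion, name=self.name,
        )


def spin_position(phantom: Phantom, t: float) -> tuple:
    """Positions (x, y, z) of every spin at time ``t`` (m).

    With no motion field the positions are time-invariant; otherwise the
    displacement field evaluated at the initial positions is added.
    """
    if phantom.motion is None:
        return phantom.x, phantom.y, phantom.z
    ux, uy, uz = phantom.motion(phantom.x, phantom.y, phantom.z, t)
    return phantom.x + ux, phantom.y + uy, phantom.z + uz


@dataclass
class RFEvent:
    """RF pulse: complex envelope samples held piecewise-constant.

    ``amplitude`` holds the complex B1 samples (T); each sample lasts
    ``raster`` seconds.  ``freq_offset`` (rad/s) and ``phase_offset``
    (rad) modulate the carrier relative to the rotating frame.
    """

    amplitude: np.ndarray
    raster: float
    delay: float = 0.0
    freq_offset: float = 0.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=complex))
        if self.raster <= 0:
            raise ValueError("RFEvent.raster must be positive")
        if self.delay < 0:
            raise ValueError("RFEvent.delay must be non-negative")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("RFEvent.amplitude must be finite")

    @property
    def duration(self) -> float:
        return len(self.amplitude) * self.raster

    @property
    def end(self) -> float:
        return self.delay + self.duration


@dataclass
class GradEvent:
    """Piecewise-linear gradient waveform on one axis.

    ``times`` are vertex times relative to block start (s, strictly
    increasing); ``amplitudes`` the gradient at each vertex (T/m).  The
    waveform is zero outside the vertex span.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    axis: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.axis not in ("x", "y", "z"):
            raise ValueError("GradEvent.axis must be one of 'x', 'y', 'z'")
        if len(self.times) != len(self.amplitudes) or len(self.times) < 2:
            raise ValueError("GradEvent needs >= 2 matching vertices")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("GradEvent.times must be strictly increasing")

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def validate_limits(self, scanner: Scanner) -> None:
        if np.max(np.abs(self.amplitudes)) > scanner.Gmax * (1 + 1e-9):
            raise ValueError(
                f"gradient amplitude {np.max(np.abs(self.amplitudes)):.4g} T/m "
                f"exceeds Gmax={scanner.Gmax:.4g} T/m"
            )
        slew = np.abs(np.diff(self.amplitudes) / np.diff(self.times))
        if slew.size and np.max(slew) > scanner.Smax * (1 + 1e-9):
            raise ValueError(
                f"slew rate {np.max(slew):.4g} T/m/s exceeds "
                f"Smax={scanner.Smax:.4g} T/m/s"
            )


@dataclass
class ADCEvent:
    """Acquisition window: ``num_samples`` samples spaced by ``dwell``."""

    num_samples: int
    dwell: float
    delay: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.num_samples < 1:
            raise ValueError("ADCEvent.num_samples must be >= 1")
        if self.dwell <= 0:
            raise ValueError("ADCEvent.dwell must be positive")

    @property
    def sample_times(self) -> np.ndarray:
        """Sample times relative to block start (s)."""
        return self.delay + np.arange(self.num_samples) * self.dwell

    @property
    def end(self) -> float:
        return self.delay + (self.num_samples - 1) * self.dwell


@dataclass
class SeqBlock:
    """One sequence block: optional RF, per-axis gradients and ADC."""

    duration: float
    rf: Optional[RFEvent] = None
    gx: Optional[GradEvent] = None
    gy: Optional[GradEvent] = None
    gz: Optional[GradEvent] = None
    adc: Optional[ADCEvent] = None

    def __post_init__(self) -> None:
        tol = 1e-9
        for ev_name in ("rf", "gx", "gy", "gz", "adc"):
            ev = getattr(self, ev_name)
            if ev is not None and ev.end > self.duration + tol:
                raise ValueError(
                    f"{ev_name} event (end {ev.end:.6g} s) extends beyond "
                    f"block duration {self.duration:.6g} s"
                )

    def gradients(self):
        return [g for g in (self.gx, self.gy, self.gz) if g is not None]


@dataclass
class Sequence:
    """Ordered list of blocks plus free-form definitions (FOV, name, ...)."""

    blocks: list
    definitions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.blocks) == 0:
            raise ValueError("Sequence must contain at least one block")

    @property
    def duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @property
    def block_starts(self) -> np.ndarray:
        return np.concatenate(
            [[0.0], np.cumsum([b.duration for b in self.blocks])]
        )

    def adc_events(self):
        """(block_index, block_start_time, ADCEvent) in sequence order."""
        starts = self.block_starts
        return [
            (i, starts[i], b.adc)
            for i, b in enumerate(self.blocks)
            if b.adc is not None
        ]

    def has_rf(self) -> bool:
        return any(b.rf is not None for b in self.blocks)

    def validate(self, scanner: Scanner) -> None:
        for b in self.blocks:
            for g in b.gradients():
                g.validate_limits(scanner)


@dataclass
class DiscreteSequence:
    """Time-node representation produced by sequence-aware discretization.

    ``t`` are the node times; ``dt[i] = t[i+1] - t[i]``.  ``B1`` and the
    gradient arrays hold the field at each node; ``adc`` flags the nodes
    at which the signal is sampled.  ``adc_node_groups`` records, per ADC
    event in sequence order, the node indices of its samples.
    """

    t: np.ndarray
    B1: np.ndarray
    Gx: np.ndarray
    Gy: np.ndarray
    Gz: np.ndarray
    adc: np.ndarray
    adc_node_groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.t)
        for f in ("B1", "Gx", "Gy", "Gz", "adc"):
            if len(getattr(self, f)) != n:
                raise ValueError(f"DiscreteSequence.{f} length mismatch")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("node times must be nondecreasing")

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.t)

    @property
    def n_nodes(self) -> int:
        return len(self.t)

    def node_slice(self, i0: int, i1: int) -> "DiscreteSequence":
        """Sub-sequence over nodes ``i0..i1`` inclusive (steps i0..i1-1)."""
        sl = slice(i0, i1 + 1)
        return DiscreteSequence(
            self.t[sl], self.B1[sl], self.Gx[sl], self.Gy[sl], self.Gz[sl],
            self.adc[sl], adc_node_groups=[],
        )


@dataclass
class Mag:
    """Spin state: complex transverse plus longitudinal magnetization."""

    xy: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.atleast_1d(np.asarray(self.xy, dtype=complex))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if len(self.xy) != len(self.z):
            raise ValueError("Mag.xy and Mag.z must have equal length")

    def copy(self) -> "Mag":
        return Mag(self.xy.copy(), self.z.copy())


SPINOR_NORM_TOL = 1e-9


@dataclass
class Spinor:
    """SU(2) rotation given by Cayley-Klein parameters (alpha, beta)."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=complex)
        self.beta = np.asarray(self.beta, dtype=complex)
        norm = np.abs(self.alpha) ** 2 + np.abs(self.beta) ** 2
        if np.max(np.abs(norm - 1.0)) > SPINOR_NORM_TOL:
            raise ValueError("Spinor is not normalized: |a|^2+|b|^2 != 1")


@dataclass
class SimConfig:
    """Solver parameters.

    ``dt`` caps the node spacing during precession (needed with motion);
    ``dt_rf`` caps the node spacing inside RF pulses; ``n_blocks`` is the
    target number of simulation blocks; ``n_threads`` the number of spin
    chunks.  Results are independent of ``n_blocks`` and ``n_threads``.
    """

    dt: float = 1e-3
    dt_rf: float = 1e-5
    n_blocks: int = 20
    n_threads: int = 1
    method: str = "bloch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt_rf <= 0:
            raise ValueError("dt and dt_rf must be positive")
        if self.n_blocks < 1 or self.n_threads < 1:
            raise ValueError("n_blocks and n_threads must be >= 1")

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Readout:
    """One acquired line: sample times, complex samples, optional k-traj."""

    times: np.ndarray
    samples: np.ndarray
    traj: Optional[np.ndarray] = None  # (n, 3) in 1/m

    def __post_init__(self) -> None:
        if len(self.times) != len(self.samples):
            raise ValueError("Readout times/samples length mismatch")


@dataclass
class RawData:
    """Acquired signal organized into readouts, plus a header."""

    readouts: list
    header: dict = field(default_factory=dict)


def equilibrium_mag(phantom: Phantom) -> Mag:
    """Thermal-equilibrium state: Mxy = 0 and Mz = M0 per spin."""
    n = phantom.n_spins
    return Mag(np.zeros(n, dtype=complex), phantom.M0.astype(float).copy())


# ---------------------------------------------------------------------------
# File interfaces


def write_phantom(phantom: Phantom, path) -> None:
    """Store a phantom as HDF5: /position (N x 3, m), /M0, /T1, /T2, /dw.

    The motion field is a code-level object and is not serialized.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "position", data=np.column_stack([phantom.x, phantom.y, phantom.z])
        )
        for name in ("M0", "T1", "T2", "dw"):
            f.create_dataset(name, data=getattr(phantom, name))
        f.attrs["name"] = phantom.name


def read_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        pos = np.asarray(f["position"])
        return Phantom(
            pos[:, 0], pos[:, 1], pos[:, 2],
            np.asarray(f["M0"]), np.asarray(f["T1"]), np.asarray(f["T2"]),
            np.asarray(f["dw"]), name=str(f.attrs.get("name", "phantom")),
        )


def write_scanner(scanner: Scanner, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(scanner), f)


def read_scanner(path) -> Scanner:
    with open(path) as f:
        data = yaml.safe_load(f)
    return Scanner(**data)
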