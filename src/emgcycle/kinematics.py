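"""Elbow kinematics: angular velocity, cycle detection, and phase segmentation.

The joint angle is exported by the motion sensor as a single plane angle in
degrees, with 0 deg at the neutral posture (90 deg of anatomical elbow
flexion), positive toward flexion.  A flexion-extension (FE) cycle runs from
one flexion peak to the next; since recordings start at maximum flexion, the
cycle is ordered extension-first::

    ACC_EXT -> DEC_EXT -> ACC_FLEX -> DEC_FLEX

Within each half-cycle the acceleration phase runs from the angle extremum to
the angular-speed extremum, and the deceleration phase from the speed extremum
to the next angle extremum.  Phase intervals are half-open ``[start, end)`` in
sample indices on the angle grid and partition each cycle exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, NoCyclesError

__all__ = [
    "AngleTrace",
    "VelocityTrace",
    "Phase",
    "PhaseCycle",
    "CycleSegmentation",
    "RomSummary",
    "angular_velocity",
    "detect_cycles",
    "segment_phases",
    "summarize_rom",
    "time_normalize_cycles",
]


class Phase(str, Enum):
    """The four sub-phases of one flexion-extension cycle."""

    ACC_EXT = "Acc_Ext"
    DEC_EXT = "Dec_Ext"
    ACC_FLEX = "Acc_Flex"
    DEC_FLEX = "Dec_Flex"

    @property
    def is_flexion(self) -> bool:
        return self in (Phase.ACC_FLEX, Phase.DEC_FLEX)


#: Order in which the phases occur inside a cycle that starts at peak flexion.
PHASE_ORDER = (Phase.ACC_EXT, Phase.DEC_EXT, Phase.ACC_FLEX, Phase.DEC_FLEX)


@dataclass(frozen=True)
class AngleTrace:
    """Elbow angle time series (deg) at the motion-sensor rate (nominally 20 Hz)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("angle trace contains non-finite samples")

    @property
    def duration(self) -> float:
        """Time spanned by the samples, in seconds."""
        return (len(self.samples) - 1) / self.fs

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class VelocityTrace:
    """Angular velocity (deg/s) on the same grid as its parent angle trace."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


@dataclass(frozen=True)
class PhaseCycle:
    """One FE cycle: four half-open sample intervals plus its landmark indices."""

    spans: dict[Phase, tuple[int, int]]
    flexion_peak: int
    extension_trough: int

    @property
    def start(self) -> int:
        return self.spans[PHASE_ORDER[0]][0]

    @property
    def end(self) -> int:
        return self.spans[PHASE_ORDER[-1]][1]


@dataclass(frozen=True)
class CycleSegmentation:
    """Ordered complete cycles segmented from one angle trace."""

    cycles: list[PhaseCycle]
    fs: float

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)


@dataclass(frozen=True)
class RomSummary:
    """Per-trial range-of-motion and angular-velocity summary.

    ``rom_max``/``rom_min`` are means over cycles of the per-cycle angle
    extrema (deg); ``velocity_max``/``velocity_min`` likewise for angular
    velocity (deg/s).  ``avg_sd_rom`` and ``avg_sd_velocity`` are the mean,
    over the time-normalized cycle, of the across-cycle standard deviation at
    each normalized time point.
    """

    rom_max: float
    rom_min: float
    avg_sd_rom: float
    velocity_max: float
    velocity_min: float
    avg_sd_velocity: float
    n_cycles: int = field(default=0)


def angular_velocity(angle: AngleTrace) -> VelocityTrace:
    """Differentiate the angle trace: central differences inside, one-sided at the edges."""
    if len(angle.samples) < 3:
        raise InsufficientDataError(
            f"need at least 3 samples to differentiate, got {len(angle.samples)}"
        )
    v = np.gradient(angle.samples, 1.0 / angle.fs)
    return VelocityTrace(samples=v, fs=angle.fs)


def detect_cycles(
    angle: AngleTrace,
    prominence_frac: float = 0.2,
    bpm: float | None = None,
    min_separation_frac: float = 0.5,
) -> np.ndarray:
    """Locate flexion peaks that delimit FE cycles.

    Peaks are local maxima with prominence of at least ``prominence_frac``
    times the trace's total range; plateaus resolve to their first sample.
    When the metronome rate is known, peaks closer than
    ``min_separation_frac`` of the nominal cycle period are suppressed.
    Because the protocol starts at maximum flexion, an opening peak is
    accepted when the record's first samples dominate the opening stretch; it
    is placed at movement onset (the end of any initial resting plateau).
    The trailing edge is never counted, so the final return to flexion opens
    a partial cycle that downstream segmentation discards.

    Returns the peak sample indices (>= 2 of them).
    """
    y = angle.samples
    rng = float(np.ptp(y))
    if rng <= 0:
        raise NoCyclesError("angle trace is constant; no cycles present")
    prominence = prominence_frac * rng

    distance = None
    if bpm is not None and bpm > 0:
        cycle_period_s = 2.0 * 60.0 / bpm  # one metronome beat per half-cycle
        distance = max(1, int(round(min_separation_frac * cycle_period_s * angle.fs)))

    peaks, props = find_peaks(y, prominence=prominence, distance=distance, plateau_size=1)
    peaks = props["left_edges"].astype(int)  # earliest sample of flat-topped peaks

    # Edge peak at the start of the record (start-at-max-flexion protocol),
    # placed at movement onset: the last sample of the initial plateau.
    onset = 0
    atol = 1e-8 * rng
    while onset + 1 < len(y) and abs(y[onset + 1] - y[0]) <= atol:
        onset += 1
    lookahead = distance if distance is not None else max(2, len(y) // 8)
    window = y[onset + 1 : onset + 1 + lookahead]
    if window.size and y[onset] >= window.max() and y[onset] - y.min() >= prominence:
        if peaks.size == 0 or peaks[0] > onset + 1:
            peaks = np.concatenate([[onset], peaks])

    if len(peaks) < 2:
        raise NoCyclesError(
            f"found {len(peaks)} qualifying flexion peak(s); need >= 2 to delimit a cycle"
        )
    return peaks.astype(int)


def _interior_extremum(values: np.ndarray, lo: int, hi: int, kind: str) -> int | None:
    """Index of the first min/max of ``values`` strictly inside (lo, hi), or None."""
    if hi - lo < 2:
        return None
    seg = values[lo + 1 : hi]
    offset = int(np.argmin(seg) if kind == "min" else np.argmax(seg))
    return lo + 1 + offset


def segment_phases(
    angle: AngleTrace,
    velocity: VelocityTrace,
    cycle_peaks: np.ndarray,
) -> CycleSegmentation:
    """Split each peak-to-peak cycle into its four acceleration/deceleration phases.

    The extension trough is the angle minimum between consecutive flexion
    peaks; the phase boundaries inside each half-cycle are the angular-speed
    extrema (most negative velocity in extension, most positive in flexion).
    Ties and plateaus resolve to the earliest sample.  A half-cycle without an
    interior speed extremum is degenerate: the cycle is excluded with a
    warning.
    """
    if len(velocity.samples) != len(angle.samples):
        raise ValueError("velocity trace does not match the angle trace")
    y, v = angle.samples, velocity.samples
    cycles: list[PhaseCycle] = []
    for p0, p1 in zip(cycle_peaks[:-1], cycle_peaks[1:]):
        trough = _interior_extremum(y, int(p0), int(p1), "min")
        if trough is None:
            warnings.warn(f"cycle [{p0}, {p1}) has no interior trough; excluded")
            continue
        v_min = _interior_extremum(v, int(p0), trough, "min")
        v_max = _interior_extremum(v, trough, int(p1), "max")
        if v_min is None or v_max is None:
            warnings.warn(
                f"cycle [{p0}, {p1}) lacks an interior velocity extremum; excluded"
            )
            continue
        spans = {
            Phase.ACC_EXT: (int(p0), v_min),
            Phase.DEC_EXT: (v_min, trough),
            Phase.ACC_FLEX: (trough, v_max),
            Phase.DEC_FLEX: (v_max, int(p1)),
        }
        if any(e <= s for s, e in spans.values()):
            warnings.warn(f"cycle [{p0}, {p1}) has an empty phase interval; excluded")
            continue
        cycles.append(
            PhaseCycle(spans=spans, flexion_peak=int(p0), extension_trough=trough)
        )
    return CycleSegmentation(cycles=cycles, fs=angle.fs)


def time_normalize_cycles(
    samples: np.ndarray,
    segmentation: CycleSegmentation,
    n_points: int = 100,
) -> np.ndarray:
    """Resample each cycle of ``samples`` onto a common 0-100% grid.

    Returns an (n_cycles, n_points) matrix; each row is the signal over one
    cycle linearly interpolated to ``n_points`` including both endpoints, so
    cycle-averaged waveforms and pointwise SD bands can be computed.
    """
    if len(segmentation) == 0:
        raise NoCyclesError("segmentation contains no complete cycles")
    samples = np.asarray(samples, dtype=float)
    out = np.empty((len(segmentation), n_points))
    grid = np.linspace(0.0, 1.0, n_points)
    for i, cyc in enumerate(segmentation):
        idx = np.arange(cyc.start, cyc.end + 1)
        idx = idx[idx < len(samples)]
        x = np.linspace(0.0, 1.0, len(idx))
        out[i] = np.interp(grid, x, samples[idx])
    return out


def summarize_rom(
    angle: AngleTrace,
    velocity: VelocityTrace,
    segmentation: CycleSegmentation,
    n_points: int = 100,
) -> RomSummary:
    """Trial-level ROM / angular-velocity summary over complete cycles.

    The per-cycle flexion maximum is the angle at the cycle's own flexion-peak
    landmark (so consecutive cycles do not share the boundary peak), the
    minimum is the angle at its extension trough; velocity extremes are taken
    over the cycle span.
    """
    if len(segmentation) == 0:
        raise NoCyclesError("no complete cycles to summarize")
    y, v = angle.samples, velocity.samples
    maxs, mins, vmaxs, vmins = [], [], [], []
    for cyc in segmentation:
        sl = slice(cyc.start, min(cyc.end + 1, len(y)))
        maxs.append(y[cyc.flexion_peak])
        mins.append(y[cyc.extension_trough])
        vmaxs.append(v[sl].max())
        vmins.append(v[sl].min())
    ang_mat = time_normalize_cycles(y, segmentation, n_points)
    vel_mat = time_normalize_cycles(v, segmentation, n_points)
    ddof = 1 if len(segmentation) > 1 else 0
    return RomSummary(
        rom_max=float(np.mean(maxs)),
        rom_min=float(np.mean(mins)),
        avg_sd_rom=float(np.mean(ang_mat.std(axis=0, ddof=ddof))),
        velocity_max=float(np.mean(vmaxs)),
        velocity_min=float(np.mean(vmins)),
        avg_sd_velocity=float(np.mean(vel_mat.std(axis=0, ddof=ddof))),
        n_cycles=len(segmentation),
    )
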