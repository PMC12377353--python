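"""Synthetic elbow flexion-extension trials with known ground truth.

The generator emulates the structure of metronome-paced elbow FE recordings:

* a joint-angle trajectory of raised-cosine half-cycles alternating between a
  flexion peak (default +75 deg) and an extension trough (default -60 deg),
  one metronome beat per half-cycle, starting and ending at maximum flexion,
  with optional multiplicative jitter on half-cycle durations and a short
  resting hold at maximum flexion before and after the movement (the quiet
  lead-in/lead-out a real recording session contains);
* noise-free per-muscle activation envelopes on the angle grid: a smooth
  agonist burst per half-cycle (biceps in flexion, triceps in extension),
  phase-dependent antagonist coactivation as a fraction of the agonist
  profile, and a small tonic triceps offset emulating gravity compensation;
* raw sEMG channels as zero-mean Gaussian noise band-limited to the analysis
  passband (20-450 Hz), amplitude-modulated by the envelope upsampled to the
  EMG rate, plus an independent band-limited sensor-noise floor.

Because the antagonist envelope is (fraction x agonist) within each phase,
and the tonic component is exactly what baseline correction removes, the
ground-truth coactivation coefficient of a phase with fraction ``r`` is the
closed form ``200 r / (1 + r)`` percent.  The default fractions invert that
relation at the per-phase coactivation levels reported for healthy adults
(flexion deceleration highest, extension acceleration lowest), so end-to-end
runs of the default cohort reproduce that phase ordering.  Ground-truth
metrics are computed on the noise-free envelopes with the same baseline,
normalization and integral conventions as the processing chain, making them
recovery targets for the full noisy pipeline.  Everything is deterministic
given (protocol, activation model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, InvalidProtocolError, SamplingRateError
from .kinematics import (
    PHASE_ORDER,
    AngleTrace,
    CycleSegmentation,
    Phase,
    PhaseCycle,
)
from .metrics import cc_by_phase, muscle_synergy
from .signals import (
    EnvelopeSignal,
    EnvelopeStage,
    RawEmgSignal,
    baseline_correct,
    normalize_envelope,
)

__all__ = [
    "MovementProtocol",
    "ActivationModel",
    "SyntheticTrial",
    "generate_angle_trace",
    "generate_activation_envelopes",
    "synthesize_raw_emg",
    "generate_trial",
    "ground_truth_metrics",
    "simulate_study",
]


@dataclass(frozen=True)
class MovementProtocol:
    """Metronome-paced FE protocol parameters.

    One metronome beat paces one half-cycle (flexion on one beat, extension
    on the next), so a full cycle lasts ``2 * 60 / bpm`` seconds.  ``rest_s``
    seconds of quiet hold at maximum flexion precede and follow the movement.
    """

    bpm: float = 60.0
    n_cycles: int = 10
    flex_max: float = 75.0
    ext_min: float = -60.0
    fs_imu: float = 20.0
    fs_emg: float = 1024.0
    cycle_jitter: float = 0.05
    rest_s: float = 2.0

    def __post_init__(self) -> None:
        if self.bpm <= 0:
            raise InvalidProtocolError(f"bpm must be positive, got {self.bpm}")
        if self.n_cycles < 1:
            raise InvalidProtocolError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.flex_max <= self.ext_min:
            raise InvalidProtocolError(
                f"flex_max ({self.flex_max}) must exceed ext_min ({self.ext_min})"
            )
        if self.fs_emg <= 900:
            raise InvalidProtocolError(
                f"fs_emg must exceed 900 Hz to admit a 450 Hz passband edge, "
                f"got {self.fs_emg}"
            )
        if self.cycle_jitter < 0:
            raise InvalidProtocolError("cycle_jitter must be nonnegative")
        if self.rest_s < 0:
            raise InvalidProtocolError("rest_s must be nonnegative")

    @property
    def half_period(self) -> float:
        """Nominal half-cycle duration (one metronome beat), seconds."""
        return 60.0 / self.bpm

    @property
    def cycle_period(self) -> float:
        return 2.0 * self.half_period


def _invert_cc(cc_percent: float) -> float:
    """Antagonist fraction r such that 200 r / (1 + r) equals the given CC."""
    return cc_percent / (200.0 - cc_percent)


# Per-phase coactivation levels (percent) the default generator emulates:
# the pattern reported for healthy adults, with flexion deceleration highest
# (braking against gravity) and extension acceleration lowest.
_TARGET_CC_PERCENT = {
    Phase.ACC_FLEX: 28.07,
    Phase.DEC_FLEX: 36.66,
    Phase.ACC_EXT: 19.54,
    Phase.DEC_EXT: 27.90,
}
_DEFAULT_ANTAGONIST_FRAC = {p: _invert_cc(cc) for p, cc in _TARGET_CC_PERCENT.items()}


@dataclass(frozen=True)
class ActivationModel:
    """Noise-free muscle-activation structure of a synthetic trial.

    ``antagonist_frac`` maps each phase to the antagonist envelope as a
    fraction of the agonist profile; ``tonic_triceps`` is a constant triceps
    offset (normalized units) standing in for gravity compensation;
    ``burst_shape`` is the raised-cosine burst width as a fraction of the
    half-cycle; ``noise_floor`` is the RMS of the additive sensor noise in
    envelope units (what baseline correction is meant to remove).
    """

    agonist_peak: float = 1.0
    antagonist_frac: dict[Phase, float] = field(
        default_factory=lambda: dict(_DEFAULT_ANTAGONIST_FRAC)
    )
    tonic_triceps: float = 0.05
    burst_shape: float = 1.0
    noise_floor: float = 0.03

    def __post_init__(self) -> None:
        if self.agonist_peak <= 0:
            raise ValueError("agonist_peak must be positive")
        if self.tonic_triceps < 0:
            raise ValueError("tonic_triceps must be nonnegative")
        if not 0 < self.burst_shape <= 1:
            raise ValueError("burst_shape must be in (0, 1]")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")
        for phase in PHASE_ORDER:
            r = self.antagonist_frac.get(phase)
            if r is None or not 0 <= r < 1:
                raise ValueError(
                    f"antagonist_frac[{phase.value}] must be in [0, 1), got {r}"
                )


def _movement_breakpoints(
    protocol: MovementProtocol, rng: np.random.Generator
) -> np.ndarray:
    """Times of the angle extrema: flexion peaks at even indices, troughs at odd.

    The first breakpoint is at ``rest_s`` (movement onset); the trailing rest
    hold is not part of the breakpoints.
    """
    durations = np.full(2 * protocol.n_cycles, protocol.half_period)
    if protocol.cycle_jitter > 0:
        factors = 1.0 + protocol.cycle_jitter * rng.standard_normal(durations.size)
        durations *= np.clip(factors, 0.2, None)
    return protocol.rest_s + np.concatenate([[0.0], np.cumsum(durations)])


def _angle_from_breakpoints(
    t: np.ndarray, breakpoints: np.ndarray, flex_max: float, ext_min: float
) -> np.ndarray:
    """Piecewise raised-cosine angle; flex_max hold outside the breakpoints."""
    seg = np.clip(np.searchsorted(breakpoints, t, side="right") - 1, 0, len(breakpoints) - 2)
    t0 = breakpoints[seg]
    t1 = breakpoints[seg + 1]
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    amp = flex_max - ext_min
    shape = (np.cos(np.pi * u) + 1.0) / 2.0  # 1 at u=0, 0 at u=1
    descending = seg % 2 == 0
    angle = np.where(descending, ext_min + amp * shape, flex_max - amp * shape)
    resting = (t < breakpoints[0]) | (t > breakpoints[-1])
    return np.where(resting, flex_max, angle)


def _sample_count(duration: float, fs: float) -> int:
    # floor with a tolerance so exact-grid endpoints are kept
    return int(np.floor(duration * fs + 1e-9)) + 1


def _trial_duration(protocol: MovementProtocol, breakpoints: np.ndarray) -> float:
    return breakpoints[-1] + protocol.rest_s


def generate_angle_trace(
    protocol: MovementProtocol, seed: int | np.random.Generator = 0
) -> AngleTrace:
    """Synthesize the elbow-angle trajectory for one trial."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    breakpoints = _movement_breakpoints(protocol, rng)
    n = _sample_count(_trial_duration(protocol, breakpoints), protocol.fs_imu)
    t = np.arange(n) / protocol.fs_imu
    samples = _angle_from_breakpoints(t, breakpoints, protocol.flex_max, protocol.ext_min)
    return AngleTrace(samples=samples, fs=protocol.fs_imu)


def _truth_segmentation(
    breakpoints: np.ndarray, fs: float, n_samples: int
) -> CycleSegmentation:
    """Analytic phase boundaries mapped onto the sampling grid.

    The raised-cosine half-cycle has its angular-speed extremum exactly at the
    temporal midpoint, so phase boundaries are the breakpoints and the
    half-cycle midpoints, rounded to the nearest sample.
    """

    def idx(time: float) -> int:
        return min(int(round(time * fs)), n_samples - 1)

    cycles: list[PhaseCycle] = []
    n_cycles = (len(breakpoints) - 1) // 2
    for k in range(n_cycles):
        peak_t = breakpoints[2 * k]
        trough_t = breakpoints[2 * k + 1]
        next_peak_t = breakpoints[2 * k + 2]
        spans = {
            Phase.ACC_EXT: (idx(peak_t), idx((peak_t + trough_t) / 2)),
            Phase.DEC_EXT: (idx((peak_t + trough_t) / 2), idx(trough_t)),
            Phase.ACC_FLEX: (idx(trough_t), idx((trough_t + next_peak_t) / 2)),
            Phase.DEC_FLEX: (idx((trough_t + next_peak_t) / 2), idx(next_peak_t)),
        }
        if any(e <= s for s, e in spans.values()):
            continue
        cycles.append(
            PhaseCycle(spans=spans, flexion_peak=idx(peak_t), extension_trough=idx(trough_t))
        )
    return CycleSegmentation(cycles=cycles, fs=fs)


def _burst_profile(u: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine (Hann) bump on normalized half-cycle time u in [0, 1]."""
    centered = (u - 0.5) / width
    profile = 0.5 * (1.0 + np.cos(2.0 * np.pi * centered))
    return np.where(np.abs(centered) <= 0.5, profile, 0.0)


def generate_activation_envelopes(
    protocol: MovementProtocol,
    model: ActivationModel,
    angle: AngleTrace,
    breakpoints: np.ndarray | None = None,
) -> tuple[EnvelopeSignal, EnvelopeSignal]:
    """Noise-free biceps and triceps activation envelopes on the angle grid.

    The biceps is silent at rest; the triceps carries its tonic offset
    throughout.  If the half-cycle breakpoints are not supplied they are
    re-derived for the jitter-free protocol; for jittered trials use
    :func:`generate_trial`, which threads the realized breakpoints through.
    """
    if breakpoints is None:
        if protocol.cycle_jitter > 0:
            raise AlignmentError(
                "breakpoints must be supplied for a jittered protocol; "
                "use generate_trial"
            )
        breakpoints = _movement_breakpoints(protocol, np.random.default_rng(0))
    n = len(angle.samples)
    expected = _sample_count(_trial_duration(protocol, breakpoints), protocol.fs_imu)
    if abs(n - expected) > 1:
        raise AlignmentError(f"angle trace has {n} samples; protocol implies {expected}")
    t = np.arange(n) / protocol.fs_imu
    seg = np.clip(np.searchsorted(breakpoints, t, side="right") - 1, 0, len(breakpoints) - 2)
    u = np.clip((t - breakpoints[seg]) / (breakpoints[seg + 1] - breakpoints[seg]), 0.0, 1.0)
    moving = (t >= breakpoints[0]) & (t <= breakpoints[-1])
    burst = np.where(moving, model.agonist_peak * _burst_profile(u, model.burst_shape), 0.0)
    is_flexion_half = (seg % 2 == 1) & moving  # odd segments ascend toward flexion
    is_extension_half = (seg % 2 == 0) & moving
    is_second_quarter = u >= 0.5

    frac = np.zeros(n)
    frac[is_extension_half & ~is_second_quarter] = model.antagonist_frac[Phase.ACC_EXT]
    frac[is_extension_half & is_second_quarter] = model.antagonist_frac[Phase.DEC_EXT]
    frac[is_flexion_half & ~is_second_quarter] = model.antagonist_frac[Phase.ACC_FLEX]
    frac[is_flexion_half & is_second_quarter] = model.antagonist_frac[Phase.DEC_FLEX]

    biceps = np.where(is_flexion_half, burst, frac * burst)
    triceps = np.where(is_flexion_half, frac * burst, burst) + model.tonic_triceps

    def mk(y: np.ndarray, muscle: str) -> EnvelopeSignal:
        return EnvelopeSignal(
            samples=y, fs=protocol.fs_imu, stage=EnvelopeStage.OVERSAMPLED, muscle=muscle
        )

    return mk(biceps, "biceps"), mk(triceps, "triceps")


def _unit_rms_carrier(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    noise = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, noise)
    rms = float(np.sqrt(np.mean(carrier**2)))
    return carrier / rms if rms > 0 else carrier


def synthesize_raw_emg(
    envelope: EnvelopeSignal,
    fs_emg: float = 1024.0,
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] = (20.0, 450.0),
    noise_floor: float = 0.0,
    muscle: str | None = None,
) -> RawEmgSignal:
    """Raw sEMG as band-limited Gaussian noise amplitude-modulated by an envelope.

    The carrier is white Gaussian noise band-passed to ``band`` and scaled to
    unit RMS, so the local RMS of the output tracks the envelope value.
    ``noise_floor`` adds an independent band-limited noise channel of that RMS
    (sensor noise); the default of 0 makes a zero envelope map to an all-zero
    signal.  The output is deterministic given the seed.
    """
    if fs_emg <= 900:
        raise SamplingRateError(
            f"fs_emg must exceed 900 Hz to admit a 450 Hz passband edge, got {fs_emg}"
        )
    if (envelope.samples < 0).any():
        raise ValueError("envelope must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = (len(envelope.samples) - 1) / envelope.fs
    n = _sample_count(duration, fs_emg)
    samples = np.zeros(n)
    carrier = _unit_rms_carrier(n, fs_emg, band, rng)
    t_emg = np.arange(n) / fs_emg
    t_env = np.arange(len(envelope.samples)) / envelope.fs
    env_up = np.interp(t_emg, t_env, envelope.samples)
    samples += env_up * carrier
    if noise_floor > 0:
        samples += noise_floor * _unit_rms_carrier(n, fs_emg, band, rng)
    return RawEmgSignal(samples=samples, fs=fs_emg, muscle=muscle or envelope.muscle)


@dataclass(frozen=True)
class SyntheticTrial:
    """One simulated trial: raw signals, noise-free envelopes, and ground truth."""

    protocol: MovementProtocol
    model: ActivationModel
    biceps_raw: RawEmgSignal
    triceps_raw: RawEmgSignal
    angle: AngleTrace
    biceps_envelope: EnvelopeSignal
    triceps_envelope: EnvelopeSignal
    truth_segmentation: CycleSegmentation
    truth_cc: dict[str, float]
    truth_synergy: dict[str, dict[str, float]]
    seed: int
    subject: str = ""

    def __post_init__(self) -> None:
        # EMG and angle streams must cover the same duration (within one IMU sample)
        d_emg = (len(self.biceps_raw.samples) - 1) / self.biceps_raw.fs
        if abs(d_emg - self.angle.duration) > 1.0 / self.angle.fs:
            raise AlignmentError(
                f"EMG duration {d_emg:.3f} s vs angle duration "
                f"{self.angle.duration:.3f} s exceeds one IMU sample"
            )


def ground_truth_metrics(
    biceps_env: EnvelopeSignal,
    triceps_env: EnvelopeSignal,
    segmentation: CycleSegmentation,
    baseline_samples: int = 30,
    noise_floor: float = 0.0,
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Per-phase CC (%) and synergy shares from noise-free envelopes.

    Each envelope goes through the same conventions as the processing chain —
    quiet-window baseline offset (which removes the tonic component exactly on
    noise-free data), peak normalization, trapezoidal integrals — so the
    result is the exact target the noisy pipeline estimates.
    """

    del noise_floor  # reserved; the analytic target ignores the sensor floor

    def condition(env: EnvelopeSignal) -> EnvelopeSignal:
        staged = EnvelopeSignal(
            samples=env.samples, fs=env.fs, stage=EnvelopeStage.OVERSAMPLED, muscle=env.muscle
        )
        return normalize_envelope(baseline_correct(staged, n_samples=baseline_samples))

    b, t = condition(biceps_env), condition(triceps_env)
    cc = cc_by_phase(b, t, segmentation)
    syn = muscle_synergy(b, t, segmentation)
    truth_cc = {k: float(v) for k, v in cc.phase_means().items()}
    means = syn.muscle_means()
    truth_synergy = {
        muscle: {
            "flexion_pct": float(means.loc[muscle, "flexion_pct"]),
            "extension_pct": float(means.loc[muscle, "extension_pct"]),
        }
        for muscle in means.index
    }
    return truth_cc, truth_synergy


def generate_trial(
    protocol: MovementProtocol = MovementProtocol(),
    model: ActivationModel = ActivationModel(),
    seed: int = 0,
    subject: str = "",
) -> SyntheticTrial:
    """Simulate one complete trial deterministically from (protocol, model, seed)."""
    ss = np.random.SeedSequence(seed)
    rng_timing, rng_biceps, rng_triceps = (np.random.default_rng(s) for s in ss.spawn(3))
    breakpoints = _movement_breakpoints(protocol, rng_timing)
    n = _sample_count(_trial_duration(protocol, breakpoints), protocol.fs_imu)
    t = np.arange(n) / protocol.fs_imu
    angle = AngleTrace(
        samples=_angle_from_breakpoints(t, breakpoints, protocol.flex_max, protocol.ext_min),
        fs=protocol.fs_imu,
    )
    biceps_env, triceps_env = generate_activation_envelopes(
        protocol, model, angle, breakpoints=breakpoints
    )
    truth_seg = _truth_segmentation(breakpoints, protocol.fs_imu, n)
    truth_cc, truth_synergy = ground_truth_metrics(
        biceps_env, triceps_env, truth_seg, noise_floor=model.noise_floor
    )
    biceps_raw = synthesize_raw_emg(
        biceps_env, protocol.fs_emg, rng_biceps, noise_floor=model.noise_floor
    )
    triceps_raw = synthesize_raw_emg(
        triceps_env, protocol.fs_emg, rng_triceps, noise_floor=model.noise_floor
    )
    return SyntheticTrial(
        protocol=protocol,
        model=model,
        biceps_raw=biceps_raw,
        triceps_raw=triceps_raw,
        angle=angle,
        biceps_envelope=biceps_env,
        triceps_envelope=triceps_env,
        truth_segmentation=truth_seg,
        truth_cc=truth_cc,
        truth_synergy=truth_synergy,
        seed=seed,
        subject=subject,
    )


def simulate_study(
    n_subjects: int = 20,
    speeds: tuple[float, ...] = (42.0, 60.0, 78.0),
    n_cycles: int = 10,
    base_model: ActivationModel = ActivationModel(),
    subject_scale_sd: float = 0.25,
    phase_frac_sd: float = 0.015,
    cycle_jitter: float = 0.05,
    seed: int = 0,
) -> list[SyntheticTrial]:
    """Simulate a cohort: every subject performs every speed once.

    Between-subject variability enters as one log-normal multiplier per
    subject on all antagonist fractions (subjects differ in overall
    coactivation level) plus small independent per-phase perturbations; no
    systematic speed effect is injected, matching the healthy-adult finding
    that coactivation depends on movement phase but not on metronome speed.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    trials: list[SyntheticTrial] = []
    max_seed = 2**31 - 1
    for s in range(n_subjects):
        scale = float(np.exp(subject_scale_sd * rng.standard_normal()))
        frac = {}
        for phase in PHASE_ORDER:
            r = base_model.antagonist_frac[phase] * scale
            r += phase_frac_sd * rng.standard_normal()
            frac[phase] = float(np.clip(r, 0.0, 0.95))
        model = ActivationModel(
            agonist_peak=base_model.agonist_peak,
            antagonist_frac=frac,
            tonic_triceps=base_model.tonic_triceps,
            burst_shape=base_model.burst_shape,
            noise_floor=base_model.noise_floor,
        )
        for bpm in speeds:
            protocol = MovementProtocol(bpm=bpm, n_cycles=n_cycles, cycle_jitter=cycle_jitter)
            trial_seed = int(rng.integers(max_seed))
            trials.append(
                generate_trial(protocol, model, seed=trial_seed, subject=f"S{s + 1:02d}")
            )
    return trials
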