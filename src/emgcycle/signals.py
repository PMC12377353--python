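"""Surface-EMG conditioning: band-pass filter, RMS envelope, resampling,
baseline correction and per-recording normalization.

The conditioning chain turns a raw sEMG channel (nominally 1,024 Hz) into the
normalized activity envelope the coactivation and synergy metrics consume:

1. fourth-order Butterworth band-pass, 20-450 Hz, applied forward-backward
   (zero phase) so the envelope stays aligned with the joint-angle trace;
2. block RMS over non-overlapping 0.25-s windows, which maps 1,024 Hz input
   to a 4-Hz envelope;
3. linear-interpolation resampling onto the 20-Hz angle grid;
4. baseline correction: offset = mean - 3*SD over a window of samples around
   the envelope minimum, subtracted and clamped at zero;
5. normalization to the maximum contraction peak of the recording, giving a
   dimensionless envelope in [0, 1] per muscle and per recording.

Each :class:`EnvelopeSignal` carries its processing ``stage``; operations
check the stage of their input so the chain cannot be applied out of order.
MVC-based normalization is deliberately not offered: the per-recording peak
reference keeps the metrics applicable to populations where a reliable
maximum voluntary contraction cannot be obtained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InsufficientDataError, StageOrderError

__all__ = [
    "RawEmgSignal",
    "FilterSpec",
    "EnvelopeStage",
    "EnvelopeSignal",
    "bandpass_filter",
    "rms_envelope",
    "resample_envelope",
    "baseline_correct",
    "normalize_envelope",
    "process_emg",
]


@dataclass(frozen=True)
class RawEmgSignal:
    """One muscle channel of raw (or filtered) sEMG in arbitrary amplitude units."""

    samples: np.ndarray
    fs: float
    muscle: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("raw EMG contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design: order and (low, high) corner frequencies in Hz."""

    order: int = 4
    band: tuple[float, float] = (20.0, 450.0)

    def validate_for(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ConfigurationError(f"band edges must satisfy 0 < low < high, got {self.band}")
        if high >= fs / 2:
            raise ConfigurationError(
                f"high edge {high} Hz is at or above Nyquist ({fs / 2} Hz)"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate_for(fs)
        return sps.butter(self.order, self.band, btype="bandpass", fs=fs, output="sos")


class EnvelopeStage(str, Enum):
    RMS = "rms"
    OVERSAMPLED = "oversampled"
    BASELINE_CORRECTED = "baseline_corrected"
    NORMALIZED = "normalized"


#: Required predecessor for each envelope stage transition.
_PREVIOUS = {
    EnvelopeStage.OVERSAMPLED: EnvelopeStage.RMS,
    EnvelopeStage.BASELINE_CORRECTED: EnvelopeStage.OVERSAMPLED,
    EnvelopeStage.NORMALIZED: EnvelopeStage.BASELINE_CORRECTED,
}


@dataclass(frozen=True)
class EnvelopeSignal:
    """Rectified/smoothed muscle-activity envelope with its processing stage."""

    samples: np.ndarray
    fs: float
    stage: EnvelopeStage
    muscle: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        """Duration covered by the envelope, in seconds (one window per sample)."""
        return len(self.samples) / self.fs

    def time(self) -> np.ndarray:
        """Window-center timestamps."""
        return (np.arange(len(self.samples)) + 0.5) / self.fs


def _require_stage(env: EnvelopeSignal, target: EnvelopeStage) -> None:
    expected = _PREVIOUS[target]
    if env.stage != expected:
        raise StageOrderError(
            f"cannot produce a {target.value} envelope from stage "
            f"'{env.stage.value}'; expected '{expected.value}'"
        )


def bandpass_filter(raw: RawEmgSignal, spec: FilterSpec = FilterSpec()) -> RawEmgSignal:
    """Zero-phase Butterworth band-pass of a raw sEMG channel.

    Forward-backward application (``sosfiltfilt``) cancels the filter's phase
    response, which matters because the per-phase integrals downstream assume
    the envelope and the angle trace share a time base.  The effective
    magnitude response is the square of the designed one.
    """
    sos = spec.sos(raw.fs)
    filtered = sps.sosfiltfilt(sos, raw.samples)
    return replace(raw, samples=filtered)


def rms_envelope(filtered: RawEmgSignal, window_s: float = 0.25) -> EnvelopeSignal:
    """Block RMS over non-overlapping windows of ``window_s`` seconds.

    The hop equals the window, so the envelope rate is exactly
    ``1 / window_s`` (0.25 s at 1,024 Hz -> 4 Hz).  A trailing partial window
    is dropped.
    """
    n = int(round(window_s * filtered.fs))
    if n < 1:
        raise ConfigurationError(
            f"window of {window_s} s spans under one sample at {filtered.fs} Hz"
        )
    n_win = len(filtered.samples) // n
    if n_win == 0:
        raise InsufficientDataError(
            f"record of {len(filtered.samples)} samples is shorter than one "
            f"{window_s} s window ({n} samples)"
        )
    blocks = filtered.samples[: n_win * n].reshape(n_win, n)
    rms = np.sqrt(np.mean(blocks**2, axis=1))
    return EnvelopeSignal(
        samples=rms, fs=1.0 / window_s, stage=EnvelopeStage.RMS, muscle=filtered.muscle
    )


def resample_envelope(
    env: EnvelopeSignal,
    target_fs: float = 20.0,
    n_out: int | None = None,
    method: str = "linear",
) -> EnvelopeSignal:
    """Oversample the RMS envelope onto the angle-trace grid.

    By default the target grid is ``0, 1/target_fs, ...`` spanning the
    envelope's duration (``floor(duration * target_fs) + 1`` points); pass
    ``n_out`` to force the output length to match an angle trace exactly.
    ``method`` is ``"linear"`` (default) or ``"hold"`` (zero-order hold).
    Values beyond the first/last window centers are held at the edge values.
    """
    _require_stage(env, EnvelopeStage.OVERSAMPLED)
    if target_fs < env.fs:
        raise ConfigurationError(
            f"target rate {target_fs} Hz is below the envelope rate {env.fs} Hz"
        )
    if n_out is None:
        n_out = int(np.floor(env.duration * target_fs)) + 1
    t_new = np.arange(n_out) / target_fs
    t_src = env.time()
    if method == "linear":
        resampled = np.interp(t_new, t_src, env.samples)
    elif method == "hold":
        idx = np.clip(np.searchsorted(t_src, t_new, side="right") - 1, 0, len(t_src) - 1)
        resampled = env.samples[idx]
    else:
        raise ConfigurationError(f"unknown resampling method {method!r}")
    return EnvelopeSignal(
        samples=resampled, fs=target_fs, stage=EnvelopeStage.OVERSAMPLED, muscle=env.muscle
    )


def baseline_correct(env: EnvelopeSignal, n_samples: int = 30) -> EnvelopeSignal:
    """Remove the resting-activity offset from an oversampled envelope.

    A window of ``n_samples`` around the point of minimum activity estimates
    the quiet-period statistics; the offset is its mean minus three standard
    deviations.  The window is placed where the ``n_samples``-point running
    mean is lowest (earliest tie), which finds the quietest stretch of the
    record rather than a single noisy dip.  Subtracting a value 3 SD below
    the quiet mean avoids clipping genuine low-level activity, at the cost of
    leaving a small positive floor.  Residual negative values are clamped to
    zero.
    """
    _require_stage(env, EnvelopeStage.BASELINE_CORRECTED)
    y = env.samples
    if len(y) < n_samples:
        raise InsufficientDataError(
            f"envelope has {len(y)} samples; baseline window needs {n_samples}"
        )
    means = np.convolve(y, np.full(n_samples, 1.0 / n_samples), mode="valid")
    lo = int(np.argmin(means))
    window = y[lo : lo + n_samples]
    offset = float(window.mean() - 3.0 * window.std(ddof=0))
    corrected = np.clip(y - offset, 0.0, None)
    return EnvelopeSignal(
        samples=corrected,
        fs=env.fs,
        stage=EnvelopeStage.BASELINE_CORRECTED,
        muscle=env.muscle,
    )


def normalize_envelope(env: EnvelopeSignal) -> EnvelopeSignal:
    """Scale a baseline-corrected envelope by its maximum contraction peak.

    The reference is the per-muscle peak of this recording, so the result is
    in [0, 1] and invariant to positive rescaling of the raw signal.  An
    all-zero envelope passes through unchanged.
    """
    _require_stage(env, EnvelopeStage.NORMALIZED)
    peak = float(env.samples.max(initial=0.0))
    scaled = env.samples / peak if peak > 0 else env.samples
    return EnvelopeSignal(
        samples=scaled, fs=env.fs, stage=EnvelopeStage.NORMALIZED, muscle=env.muscle
    )


def process_emg(
    raw: RawEmgSignal,
    spec: FilterSpec = FilterSpec(),
    window_s: float = 0.25,
    target_fs: float = 20.0,
    baseline_samples: int = 30,
    n_out: int | None = None,
    resample_method: str = "linear",
) -> EnvelopeSignal:
    """Full conditioning chain: filter -> RMS -> oversample -> baseline -> normalize."""
    filtered = bandpass_filter(raw, spec)
    env = rms_envelope(filtered, window_s=window_s)
    env = resample_envelope(env, target_fs=target_fs, n_out=n_out, method=resample_method)
    env = baseline_correct(env, n_samples=baseline_samples)
    return normalize_envelope(env)
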