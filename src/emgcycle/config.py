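"""Pipeline configuration: every tunable of the analysis chain in one place.

Defaults reproduce the standard processing choices for metronome-paced elbow
FE recordings: 20-450 Hz fourth-order Butterworth band-pass, 0.25-s block RMS
(4-Hz envelope), oversampling to the 20-Hz angle grid, a 30-sample baseline
window, peak detection at 20% prominence with half-period separation, and
trapezoidal integration.  Values are validated at load time against the
preconditions of the modules that consume them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class PipelineConfig(BaseModel):
    """Validated bundle of all pipeline tunables."""

    # sEMG conditioning
    filter_order: int = Field(4, ge=1)
    filter_low_hz: float = Field(20.0, gt=0)
    filter_high_hz: float = Field(450.0, gt=0)
    rms_window_s: float = Field(0.25, gt=0)
    envelope_fs: float = Field(20.0, gt=0)
    baseline_samples: int = Field(30, ge=2)
    resample_method: Literal["linear", "hold"] = "linear"

    # nominal acquisition rates and tolerance for validating input files
    emg_fs: float = Field(1024.0, gt=900)
    angle_fs: float = Field(20.0, gt=0)
    rate_tolerance: float = Field(0.01, gt=0)

    # cycle detection
    peak_prominence_frac: float = Field(0.2, gt=0, lt=1)
    peak_min_separation_frac: float = Field(0.5, gt=0)

    # metrics / stats variants
    synergy_denominator: Literal["per_muscle", "per_phase"] = "per_muscle"
    cohens_f_variant: Literal["partial_eta", "eta"] = "partial_eta"
    alpha: float = Field(0.05, gt=0, lt=1)

    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "PipelineConfig":
        if self.filter_low_hz >= self.filter_high_hz:
            raise ValueError("filter_low_hz must be below filter_high_hz")
        if self.filter_high_hz >= self.emg_fs / 2:
            raise ValueError("filter_high_hz must be below the EMG Nyquist rate")
        if self.envelope_fs < 1.0 / self.rms_window_s:
            raise ValueError("envelope_fs must be at least the RMS envelope rate")
        if self.rms_window_s * self.emg_fs < 1:
            raise ValueError("rms_window_s spans under one EMG sample")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        """Write the full configuration (all defaults inlined) to a YAML file."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
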