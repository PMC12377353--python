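"""End-to-end analysis: conditioning -> segmentation -> metrics -> statistics.

``process_trial`` runs one trial through the full chain and returns its
per-cycle tables; ``run_pipeline`` maps that over a list of trials (in-memory
synthetic trials or manifests pointing at interchange CSVs), aggregates tidy
tables, and fits the phase x speed factorial model when the design supports
it.  Per-trial failures are logged and skipped; an empty result set is a hard
error.  Given identical inputs, configuration and seed the pipeline output is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import PipelineConfig
from .errors import EmgCycleError, EmptyResultError
from .io import TrialManifest, read_trial
from .kinematics import (
    AngleTrace,
    CycleSegmentation,
    RomSummary,
    angular_velocity,
    detect_cycles,
    segment_phases,
    summarize_rom,
)
from .metrics import CoactivationResult, SynergyResult, cc_by_phase, muscle_synergy
from .signals import FilterSpec, RawEmgSignal, process_emg
from .simulate import SyntheticTrial
from .stats import CoactivationAnova, CoactivationAnovaResults

__all__ = ["TrialResult", "PipelineResult", "process_trial", "run_pipeline"]

logger = logging.getLogger("emgcycle")


@dataclass(frozen=True)
class TrialResult:
    """All per-trial outputs of the processing chain."""

    subject: str
    speed_bpm: float
    coactivation: CoactivationResult
    synergy: SynergyResult
    rom: RomSummary
    segmentation: CycleSegmentation
    biceps_envelope: np.ndarray
    triceps_envelope: np.ndarray


@dataclass
class PipelineResult:
    """Aggregated study outputs: tidy tables plus the fitted factorial model."""

    cc_table: pd.DataFrame  # subject, speed_bpm, cycle, phase, cc
    synergy_table: pd.DataFrame  # subject, speed_bpm, cycle, muscle, flexion_pct, extension_pct
    rom_table: pd.DataFrame  # one row per trial
    trials: list[TrialResult]
    anova: CoactivationAnovaResults | None = None
    log: list[str] = field(default_factory=list)

    def cell_means(self) -> pd.DataFrame:
        """Mean CC per subject x speed x phase cell (the ANOVA observations)."""
        return (
            self.cc_table.groupby(["subject", "speed_bpm", "phase"], sort=False)["cc"]
            .mean()
            .reset_index()
            .rename(columns={"speed_bpm": "speed"})
        )

    def pooled_phase_means(self) -> pd.Series:
        """Speed-pooled mean CC per phase, averaged over subject-cell means."""
        cells = self.cell_means()
        order = list(dict.fromkeys(self.cc_table["phase"]))
        return cells.groupby("phase", sort=False)["cc"].mean().reindex(order)


def process_trial(
    biceps_raw: RawEmgSignal,
    triceps_raw: RawEmgSignal,
    angle: AngleTrace,
    config: PipelineConfig | None = None,
    subject: str = "",
    speed_bpm: float | None = None,
) -> TrialResult:
    """Run one trial through conditioning, segmentation and metrics."""
    config = config or PipelineConfig()
    spec = FilterSpec(
        order=config.filter_order, band=(config.filter_low_hz, config.filter_high_hz)
    )
    envs = {}
    for raw in (biceps_raw, triceps_raw):
        envs[raw.muscle or "channel"] = process_emg(
            raw,
            spec=spec,
            window_s=config.rms_window_s,
            target_fs=config.envelope_fs,
            baseline_samples=config.baseline_samples,
            n_out=len(angle.samples),
            resample_method=config.resample_method,
        )
    biceps_env = envs.get("biceps") or list(envs.values())[0]
    triceps_env = envs.get("triceps") or list(envs.values())[-1]

    velocity = angular_velocity(angle)
    peaks = detect_cycles(
        angle,
        prominence_frac=config.peak_prominence_frac,
        bpm=speed_bpm,
        min_separation_frac=config.peak_min_separation_frac,
    )
    segmentation = segment_phases(angle, velocity, peaks)
    cc = cc_by_phase(biceps_env, triceps_env, segmentation)
    synergy = muscle_synergy(biceps_env, triceps_env, segmentation)
    rom = summarize_rom(angle, velocity, segmentation)
    return TrialResult(
        subject=subject,
        speed_bpm=float(speed_bpm or 0.0),
        coactivation=cc,
        synergy=synergy,
        rom=rom,
        segmentation=segmentation,
        biceps_envelope=biceps_env.samples,
        triceps_envelope=triceps_env.samples,
    )


def _trial_inputs(item: SyntheticTrial | TrialManifest, config: PipelineConfig):
    if isinstance(item, SyntheticTrial):
        return (
            item.biceps_raw,
            item.triceps_raw,
            item.angle,
            item.subject or f"seed{item.seed}",
            item.protocol.bpm,
        )
    biceps, triceps, angle = read_trial(item, config)
    return biceps, triceps, angle, item.subject, item.speed_bpm


def run_pipeline(
    trials: list[SyntheticTrial | TrialManifest],
    config: PipelineConfig | None = None,
    out_dir: Path | None = None,
) -> PipelineResult:
    """Process a list of trials and fit the factorial model where possible.

    ``trials`` may mix in-memory synthetic trials and manifests of interchange
    CSVs.  Tidy CSV outputs and a run log are written under ``out_dir`` when
    given.
    """
    if not trials:
        raise EmptyResultError("no trials supplied")
    config = config or PipelineConfig()
    results: list[TrialResult] = []
    log: list[str] = [f"emgcycle {_pkg_version}", f"config: {config.model_dump()}"]
    for i, item in enumerate(trials):
        try:
            biceps, triceps, angle, subject, bpm = _trial_inputs(item, config)
            results.append(
                process_trial(biceps, triceps, angle, config, subject=subject, speed_bpm=bpm)
            )
        except EmgCycleError as exc:
            msg = f"trial {i} ({getattr(item, 'subject', '?')}): skipped ({exc})"
            logger.warning(msg)
            log.append(msg)
    if not results:
        raise EmptyResultError("all trials failed processing")

    cc_rows, syn_rows, rom_rows = [], [], []
    for r in results:
        cc = r.coactivation.per_phase.assign(subject=r.subject, speed_bpm=r.speed_bpm)
        cc_rows.append(cc[["subject", "speed_bpm", "cycle", "phase", "cc"]])
        syn = r.synergy.per_cycle.assign(subject=r.subject, speed_bpm=r.speed_bpm)
        syn_rows.append(
            syn[["subject", "speed_bpm", "cycle", "muscle", "flexion_pct", "extension_pct"]]
        )
        rom_rows.append(
            {
                "subject": r.subject,
                "speed_bpm": r.speed_bpm,
                "n_cycles": r.rom.n_cycles,
                "rom_max": r.rom.rom_max,
                "rom_min": r.rom.rom_min,
                "avg_sd_rom": r.rom.avg_sd_rom,
                "velocity_max": r.rom.velocity_max,
                "velocity_min": r.rom.velocity_min,
                "avg_sd_velocity": r.rom.avg_sd_velocity,
            }
        )
    out = PipelineResult(
        cc_table=pd.concat(cc_rows, ignore_index=True),
        synergy_table=pd.concat(syn_rows, ignore_index=True),
        rom_table=pd.DataFrame(rom_rows),
        trials=results,
        log=log,
    )

    cells = out.cell_means()
    if cells["phase"].nunique() >= 2 and cells["speed"].nunique() >= 2:
        out.anova = CoactivationAnova(cells, dv="cc", factors=("phase", "speed")).fit(
            alpha=config.alpha
        )
    else:
        log.append(
            "stats stage skipped: need >= 2 levels of both phase and speed "
            f"(got {cells['phase'].nunique()} phase, {cells['speed'].nunique()} speed)"
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.cc_table.to_csv(out_dir / "coactivation.csv", index=False)
        out.synergy_table.to_csv(out_dir / "synergy.csv", index=False)
        out.rom_table.to_csv(out_dir / "rom_summary.csv", index=False)
        if out.anova is not None:
            out.anova.anova_table.to_csv(out_dir / "anova.csv")
            out.anova.tukey("phase").to_csv(out_dir / "tukey_phase.csv", index=False)
            out.anova.tukey("speed").to_csv(out_dir / "tukey_speed.csv", index=False)
        (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
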