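"""Plain-CSV trial interchange and manifest handling.

The study device exports through a proprietary app, so the package defines
its own text interchange format per trial:

* EMG CSV with columns ``time_s, biceps_uV, triceps_uV`` at the EMG rate;
* angle CSV with columns ``time_s, angle_deg`` at the motion-sensor rate;
* an optional JSON sidecar with simulation ground truth.

Sampling rates are inferred from the time columns and validated against the
configured nominal rates within a relative tolerance.  A hook is provided for
adapting exports from the original acquisition system once their schema is
known; it deliberately raises rather than guessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ParseError
from .kinematics import AngleTrace
from .signals import RawEmgSignal

__all__ = [
    "TrialManifest",
    "read_trial",
    "write_trial_csvs",
    "read_truth_json",
    "discover_manifests",
]

EMG_COLUMNS = ("time_s", "biceps_uV", "triceps_uV")
ANGLE_COLUMNS = ("time_s", "angle_deg")


@dataclass(frozen=True)
class TrialManifest:
    """Pointers to the files of one recorded (or simulated) trial."""

    subject: str
    speed_bpm: float
    emg_path: Path
    angle_path: Path
    truth_path: Path | None = None

    def __post_init__(self) -> None:
        if self.speed_bpm <= 0:
            raise ParseError(f"speed_bpm must be positive, got {self.speed_bpm}")


def _read_timeseries(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise ParseError(
            f"{path}: time_s not strictly increasing at row {row + 1} "
            f"(t={t[row]!r} follows t={t[row - 1]!r})"
        )
    if not np.all(np.isfinite(df[list(columns)].to_numpy(dtype=float))):
        raise ParseError(f"{path}: non-finite values present")
    return df


def _infer_fs(t: np.ndarray, nominal: float, tol: float, path: Path) -> float:
    fs = 1.0 / float(np.median(np.diff(t)))
    if abs(fs - nominal) / nominal > tol:
        raise ParseError(
            f"{path}: inferred rate {fs:.3f} Hz deviates from nominal "
            f"{nominal} Hz by more than {tol:.1%}"
        )
    return fs


def read_trial(
    manifest: TrialManifest, config: PipelineConfig | None = None
) -> tuple[RawEmgSignal, RawEmgSignal, AngleTrace]:
    """Load and validate one trial: (biceps raw, triceps raw, angle trace)."""
    config = config or PipelineConfig()
    emg = _read_timeseries(Path(manifest.emg_path), EMG_COLUMNS)
    ang = _read_timeseries(Path(manifest.angle_path), ANGLE_COLUMNS)
    fs_emg = _infer_fs(
        emg["time_s"].to_numpy(), config.emg_fs, config.rate_tolerance, Path(manifest.emg_path)
    )
    fs_ang = _infer_fs(
        ang["time_s"].to_numpy(), config.angle_fs, config.rate_tolerance, Path(manifest.angle_path)
    )
    biceps = RawEmgSignal(emg["biceps_uV"].to_numpy(), fs=fs_emg, muscle="biceps")
    triceps = RawEmgSignal(emg["triceps_uV"].to_numpy(), fs=fs_emg, muscle="triceps")
    angle = AngleTrace(ang["angle_deg"].to_numpy(), fs=fs_ang)
    return biceps, triceps, angle


def write_trial_csvs(
    out_dir: Path,
    stem: str,
    biceps: RawEmgSignal,
    triceps: RawEmgSignal,
    angle: AngleTrace,
    truth: dict | None = None,
) -> TrialManifest:
    """Write one trial in the interchange format; returns its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emg_path = out_dir / f"{stem}_emg.csv"
    ang_path = out_dir / f"{stem}_angle.csv"
    t_emg = np.arange(len(biceps.samples)) / biceps.fs
    pd.DataFrame(
        {"time_s": t_emg, "biceps_uV": biceps.samples, "triceps_uV": triceps.samples}
    ).to_csv(emg_path, index=False)
    pd.DataFrame(
        {"time_s": angle.time(), "angle_deg": angle.samples}
    ).to_csv(ang_path, index=False)
    truth_path = None
    if truth is not None:
        truth_path = out_dir / f"{stem}_truth.json"
        truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    meta = truth or {}
    return TrialManifest(
        subject=str(meta.get("subject", stem)),
        speed_bpm=float(meta.get("speed_bpm", 0) or 60.0),
        emg_path=emg_path,
        angle_path=ang_path,
        truth_path=truth_path,
    )


def read_truth_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def discover_manifests(data_dir: Path) -> list[TrialManifest]:
    """Build manifests from ``<stem>_emg.csv`` / ``<stem>_angle.csv`` pairs.

    When a ``<stem>_truth.json`` sidecar exists, subject and speed metadata
    are taken from it; otherwise the stem is parsed as ``<subject>_<bpm>bpm``.
    """
    data_dir = Path(data_dir)
    manifests = []
    for emg_path in sorted(data_dir.glob("*_emg.csv")):
        stem = emg_path.name[: -len("_emg.csv")]
        angle_path = data_dir / f"{stem}_angle.csv"
        if not angle_path.exists():
            raise ParseError(f"{emg_path}: no matching angle file {angle_path.name}")
        truth_path = data_dir / f"{stem}_truth.json"
        subject, speed = stem, 60.0
        if truth_path.exists():
            meta = read_truth_json(truth_path)
            subject = str(meta.get("subject", stem))
            speed = float(meta.get("speed_bpm", speed))
        elif "_" in stem and stem.rsplit("_", 1)[1].endswith("bpm"):
            subject, tail = stem.rsplit("_", 1)
            try:
                speed = float(tail[:-3])
            except ValueError as exc:
                raise ParseError(f"{emg_path}: cannot parse speed from {tail!r}") from exc
        manifests.append(
            TrialManifest(
                subject=subject,
                speed_bpm=speed,
                emg_path=emg_path,
                angle_path=angle_path,
                truth_path=truth_path if truth_path.exists() else None,
            )
        )
    return manifests


def load_study_export(path: Path):
    """Adapter hook for the original acquisition system's export format.

    The export schema of the study's recordings is not publicly documented;
    rather than guess at column layouts, this hook raises until a schema is
    provided.  Convert exports to the interchange CSVs described in this
    module to analyze them.
    """
    raise NotImplementedError(
        "the acquisition-system export schema is unknown; convert recordings "
        "to the documented interchange CSV format instead"
    )
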