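"""Coactivation coefficient and muscle-synergy (area-share) metrics.

The coactivation coefficient (CC) follows the Falconer-Winter construction:
with ``Ag`` and ``Antag`` the areas under the agonist and antagonist activity
envelopes over an interval, and the "common area" the integral of their
pointwise minimum,

    CC = 2 * common / (Ag + Antag) * 100        (percent)

CC is 100 for identical envelopes, 0 for envelopes with disjoint support, and
is symmetric in its two arguments.  Both areas zero defines CC = 0 so quiet
phases do not poison aggregates.

Muscle synergy here is an area-share statistic, not a factorization: for each
muscle and cycle, the percentage of that muscle's envelope area falling in the
flexion vs the extension phases (the two shares sum to 100).  A secondary
between-muscle share (biceps vs triceps within each phase) is also computed.

Integrals use the trapezoidal rule on the 20-Hz envelope grid.  A phase
interval ``[start, end)`` is integrated over the closed panel span
``start..end`` so that the four phase integrals of a cycle sum exactly to the
full-cycle integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .kinematics import PHASE_ORDER, CycleSegmentation, Phase
from .signals import EnvelopeSignal

__all__ = [
    "CoactivationResult",
    "SynergyResult",
    "coactivation_coefficient",
    "cc_by_phase",
    "muscle_synergy",
]


def coactivation_coefficient(ag: np.ndarray, antag: np.ndarray, dx: float = 1.0) -> float:
    """Coactivation coefficient (%) of two aligned, nonnegative envelope segments.

    ``dx`` is the sample spacing; it cancels in the ratio and only matters if
    the caller compares raw areas.
    """
    ag = np.asarray(ag, dtype=float)
    antag = np.asarray(antag, dtype=float)
    if ag.shape != antag.shape:
        raise AlignmentError(
            f"envelope segments differ in length: {ag.shape} vs {antag.shape}"
        )
    if (ag < 0).any() or (antag < 0).any():
        raise ValueError("envelope segments must be nonnegative")
    common = np.trapezoid(np.minimum(ag, antag), dx=dx)
    total = np.trapezoid(ag, dx=dx) + np.trapezoid(antag, dx=dx)
    if total == 0:
        return 0.0
    return float(np.clip(2.0 * common / total * 100.0, 0.0, 100.0))


def _phase_slice(samples: np.ndarray, span: tuple[int, int]) -> np.ndarray:
    """Samples over the closed panel span of a half-open phase interval."""
    start, end = span
    return samples[start : min(end + 1, len(samples))]


def _check_alignment(env: EnvelopeSignal, segmentation: CycleSegmentation) -> None:
    if len(segmentation) == 0:
        raise ValueError("segmentation holds no complete cycles")
    last = segmentation.cycles[-1].end
    if last > len(env.samples):
        raise AlignmentError(
            f"segmentation extends to sample {last} but envelope has "
            f"{len(env.samples)} samples"
        )
    if abs(env.fs - segmentation.fs) > 1e-9:
        raise AlignmentError(
            f"envelope rate {env.fs} Hz does not match segmentation grid "
            f"{segmentation.fs} Hz"
        )


@dataclass(frozen=True)
class CoactivationResult:
    """Per-cycle and per-phase coactivation coefficients for one trial.

    ``per_phase`` has one row per (cycle, phase) with columns ``cycle``,
    ``phase``, ``agonist`` and ``cc``; ``per_cycle`` one row per cycle with
    the whole-cycle CC.
    """

    per_phase: pd.DataFrame
    per_cycle: pd.DataFrame

    def phase_means(self) -> pd.Series:
        """Mean CC (%) per phase across cycles, in within-cycle phase order."""
        m = self.per_phase.groupby("phase", sort=False)["cc"].mean()
        return m.reindex([p.value for p in PHASE_ORDER])

    def phase_sds(self) -> pd.Series:
        s = self.per_phase.groupby("phase", sort=False)["cc"].std(ddof=1)
        return s.reindex([p.value for p in PHASE_ORDER])

    def cycle_mean(self) -> float:
        return float(self.per_cycle["cc"].mean())


def cc_by_phase(
    biceps: EnvelopeSignal,
    triceps: EnvelopeSignal,
    segmentation: CycleSegmentation,
    dx: float | None = None,
) -> CoactivationResult:
    """Evaluate the CC on every phase interval and on each full cycle.

    The agonist is the biceps in flexion phases and the triceps in extension
    phases; the CC itself is symmetric, so the labeling affects only
    reporting.  Empty phase intervals are skipped with a warning.
    """
    if len(biceps.samples) != len(triceps.samples):
        raise AlignmentError(
            f"biceps and triceps envelopes differ in length: "
            f"{len(biceps.samples)} vs {len(triceps.samples)}"
        )
    _check_alignment(biceps, segmentation)
    if dx is None:
        dx = 1.0 / biceps.fs
    b, t = biceps.samples, triceps.samples

    phase_rows, cycle_rows = [], []
    for i, cyc in enumerate(segmentation):
        for phase in PHASE_ORDER:
            span = cyc.spans[phase]
            if span[1] <= span[0]:
                warnings.warn(f"cycle {i}: empty {phase.value} interval skipped")
                continue
            bseg = _phase_slice(b, span)
            tseg = _phase_slice(t, span)
            ag, antag = (bseg, tseg) if phase.is_flexion else (tseg, bseg)
            phase_rows.append(
                {
                    "cycle": i,
                    "phase": phase.value,
                    "agonist": "biceps" if phase.is_flexion else "triceps",
                    "cc": coactivation_coefficient(ag, antag, dx=dx),
                }
            )
        full = (cyc.start, cyc.end)
        cycle_rows.append(
            {
                "cycle": i,
                "cc": coactivation_coefficient(
                    _phase_slice(b, full), _phase_slice(t, full), dx=dx
                ),
            }
        )
    return CoactivationResult(
        per_phase=pd.DataFrame(phase_rows), per_cycle=pd.DataFrame(cycle_rows)
    )


@dataclass(frozen=True)
class SynergyResult:
    """Flexion/extension activity shares per muscle and cycle.

    ``per_cycle`` columns: ``cycle``, ``muscle``, ``flexion_pct``,
    ``extension_pct`` (summing to 100 per muscle with nonzero area; NaN when a
    muscle is silent over the whole cycle).  ``between_muscle`` gives the
    complementary view: the biceps share of the summed two-muscle area within
    each half-movement.
    """

    per_cycle: pd.DataFrame
    between_muscle: pd.DataFrame

    def muscle_means(self) -> pd.DataFrame:
        return self.per_cycle.groupby("muscle", sort=False)[
            ["flexion_pct", "extension_pct"]
        ].mean()


def muscle_synergy(
    biceps: EnvelopeSignal,
    triceps: EnvelopeSignal,
    segmentation: CycleSegmentation,
    dx: float | None = None,
) -> SynergyResult:
    """Split each muscle's per-cycle envelope area between flexion and extension."""
    if len(biceps.samples) != len(triceps.samples):
        raise AlignmentError("biceps and triceps envelopes differ in length")
    _check_alignment(biceps, segmentation)
    if dx is None:
        dx = 1.0 / biceps.fs

    def half_area(samples: np.ndarray, cyc, flexion: bool) -> float:
        phases = [p for p in PHASE_ORDER if p.is_flexion == flexion]
        return float(
            sum(np.trapezoid(_phase_slice(samples, cyc.spans[p]), dx=dx) for p in phases)
        )

    rows, between = [], []
    for i, cyc in enumerate(segmentation):
        areas = {}
        for muscle, samples in (("biceps", biceps.samples), ("triceps", triceps.samples)):
            flex = half_area(samples, cyc, flexion=True)
            ext = half_area(samples, cyc, flexion=False)
            total = flex + ext
            areas[muscle] = (flex, ext)
            if total == 0:
                warnings.warn(f"cycle {i}: {muscle} has zero area; synergy undefined")
                rows.append(
                    {"cycle": i, "muscle": muscle, "flexion_pct": np.nan, "extension_pct": np.nan}
                )
            else:
                rows.append(
                    {
                        "cycle": i,
                        "muscle": muscle,
                        "flexion_pct": 100.0 * flex / total,
                        "extension_pct": 100.0 * ext / total,
                    }
                )
        for j, half in enumerate(("flexion", "extension")):
            pair_total = areas["biceps"][j] + areas["triceps"][j]
            between.append(
                {
                    "cycle": i,
                    "half": half,
                    "biceps_pct": 100.0 * areas["biceps"][j] / pair_total
                    if pair_total > 0
                    else np.nan,
                }
            )
    return SynergyResult(per_cycle=pd.DataFrame(rows), between_muscle=pd.DataFrame(between))
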