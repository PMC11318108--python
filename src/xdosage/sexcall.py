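"""Threshold-based genetic sex calls from X-dosage fold changes.

A two-X individual carries the same relative dosage of X-linked and
autosomal loci as the female reference (fold ~ 1.0); a single-X individual
carries half (fold ~ 0.5).  Per marker, fold < 0.7 calls male, fold > 0.8
calls female, and the band [0.7, 0.8] is left unspecified (both thresholds
strict, so exactly 0.7 or 0.8 is unspecified).

The per-sample consensus applies, in order:

1. call every marker;
2. all markers unspecified -> sample removed (no assignment possible);
3. conflicting determinate calls (male and female) -> removed in strict
   mode, majority vote in non-strict mode (ties removed);
4. standard deviation of the available X-marker folds above 0.3 -> removed
   (the calls must converge on the same dosage, not just the same side of a
   threshold); with a single available fold the SD is undefined and passes.

A unanimous male call is reported as ``male_singleX`` (XY and X0 are
indistinguishable without Y-specific markers), a unanimous female call as
``female_XX``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .quantify import FOLD_COLUMNS

CALL_MALE = "male"
CALL_FEMALE = "female"
CALL_UNSPECIFIED = "unspecified"
CALL_MISSING = "missing"

CONSENSUS_FEMALE = "female_XX"
CONSENSUS_MALE = "male_singleX"
CONSENSUS_UNSPECIFIED = "unspecified"
CONSENSUS_REMOVED = "removed"

REASON_ALL_UNSPECIFIED = "all_unspecified"
REASON_CONFLICT = "conflicting_calls"
REASON_MARKER_SD = "marker_sd_exceeded"
REASON_QC = "qc_failed"

ASSIGNMENT_COLUMNS = (
    "sample_id",
    "consensus",
    "removal_reason",
    "mean_fold",
    "marker_sd",
)


@dataclass(frozen=True)
class CallParams:
    """Decision thresholds.  Defaults are the published 0.7/0.8/0.3 values."""

    male_below: float = 0.7      # fold strictly below -> male
    female_above: float = 0.8    # fold strictly above -> female
    marker_sd_max: float = 0.3   # max SD of X-marker folds (concordance)
    strict_conflicts: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.male_below <= self.female_above:
            raise ValueError("need 0 < male_below <= female_above")
        if self.marker_sd_max < 0:
            raise ValueError("marker_sd_max must be >= 0")


@dataclass(frozen=True)
class SexAssignment:
    """Per-marker calls plus the consensus genotype for one sample."""

    sample_id: str
    per_marker_calls: Mapping[str, str]
    mean_fold: float
    marker_sd: float          # NaN when < 2 folds available
    consensus: str
    removal_reason: str | None = None


def call_marker(fold: float, params: CallParams = CallParams()) -> str:
    """Call one marker from its fold change (male / female / unspecified)."""
    if not fold > 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    if fold < params.male_below:
        return CALL_MALE
    if fold > params.female_above:
        return CALL_FEMALE
    return CALL_UNSPECIFIED


def consensus(
    folds: Mapping[str, float],
    params: CallParams = CallParams(),
    sample_id: str = "",
) -> SexAssignment:
    """Combine per-marker fold changes into a consensus genotype call."""
    clean = {m: float(f) for m, f in folds.items() if not math.isnan(float(f))}
    if not clean:
        raise ValueError("no fold changes provided")

    calls = {m: call_marker(f, params) for m, f in clean.items()}
    values = np.array(list(clean.values()), dtype=float)
    mean_fold = float(values.mean())
    marker_sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")

    determinate = [c for c in calls.values() if c != CALL_UNSPECIFIED]

    def removed(reason: str) -> SexAssignment:
        return SexAssignment(
            sample_id, dict(calls), mean_fold, marker_sd, CONSENSUS_REMOVED, reason
        )

    if not determinate:
        return removed(REASON_ALL_UNSPECIFIED)

    n_male = determinate.count(CALL_MALE)
    n_female = determinate.count(CALL_FEMALE)
    if n_male and n_female:
        if params.strict_conflicts:
            return removed(REASON_CONFLICT)
        if n_male == n_female:
            return removed(REASON_CONFLICT)
        winner = CALL_MALE if n_male > n_female else CALL_FEMALE
    else:
        winner = CALL_MALE if n_male else CALL_FEMALE

    if not math.isnan(marker_sd) and marker_sd > params.marker_sd_max:
        return removed(REASON_MARKER_SD)

    verdict = CONSENSUS_MALE if winner == CALL_MALE else CONSENSUS_FEMALE
    return SexAssignment(
        sample_id, dict(calls), mean_fold, marker_sd, verdict, None
    )


def assign_sex(
    folds: pd.DataFrame,
    params: CallParams = CallParams(),
    qc_failed: Iterable[str] = (),
) -> tuple[list[SexAssignment], pd.DataFrame]:
    """Consensus calls for every sample in a fold-change table.

    A sample measured on several plates contributes one fold per marker:
    repeated (sample, marker) folds are combined by geometric mean (folds
    are ratios).  Samples listed in ``qc_failed`` (discarded before any
    fold could be computed) appear in the output as removed with reason
    ``qc_failed``.

    Returns the assignment objects plus a flat summary table.
    """
    assignments: list[SexAssignment] = []
    for sample_id, sub in folds.groupby("sample_id", sort=False):
        per_marker = (
            sub.groupby("target")["fold"].apply(lambda v: float(np.exp(np.mean(np.log(v)))))
        )
        assignments.append(consensus(per_marker.to_dict(), params, str(sample_id)))

    seen = {a.sample_id for a in assignments}
    for sample_id in qc_failed:
        if sample_id in seen:
            continue
        assignments.append(
            SexAssignment(
                str(sample_id), {}, float("nan"), float("nan"),
                CONSENSUS_REMOVED, REASON_QC,
            )
        )

    return assignments, assignments_frame(assignments)


def assignments_frame(
    assignments: Iterable[SexAssignment] | pd.DataFrame,
) -> pd.DataFrame:
    """Coerce assignments to a flat table (one row per sample)."""
    if isinstance(assignments, pd.DataFrame):
        return assignments
    assignments = list(assignments)
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "consensus": [a.consensus for a in assignments],
            "removal_reason": [a.removal_reason for a in assignments],
            "mean_fold": [a.mean_fold for a in assignments],
            "marker_sd": [a.marker_sd for a in assignments],
        }
    )
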