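"""Cohort- and family-level statistics for genetic-sex assignments.

* :func:`performance` scores assignments against phenotypic sex
  (specificity / sensitivity on the samples with a determinate consensus;
  removed samples are reported as non-assignments alongside).
* :func:`filter_bias_test` checks whether QC removed samples unevenly
  between two groups (Pearson chi-squared on the 2x2 failed/passed table,
  Yates continuity correction on by default as in R's ``chisq.test``).
* :func:`single_x_proportion` estimates the fraction of single-X genotypes
  in a haplotype/stage stratum with an exact (Clopper-Pearson) binomial CI.
* :func:`family_ratios` summarizes genotype counts per brood and infers the
  mother's genotype: any single-X offspring implies a single-X mother,
  all-XX broods imply an XX mother (flagged when the brood is small enough
  that a single-X offspring could simply have been missed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import SampleAnnotation, annotations_frame
from .sexcall import (
    CONSENSUS_FEMALE,
    CONSENSUS_MALE,
    SexAssignment,
    assignments_frame,
)

_CONSENSUS_TO_SEX = {CONSENSUS_MALE: "male", CONSENSUS_FEMALE: "female"}

MOTHER_XX = "XX"
MOTHER_SINGLE_X = "singleX"
MOTHER_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PerformanceReport:
    """Assignment accuracy against phenotype for one positive class."""

    positive_class: str
    n_called: int
    n_removed: int
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    #: fraction of phenotype-positive / -negative samples that received any
    #: determinate call (removals count against these, mirroring the cost of
    #: strict filtering)
    called_fraction_positive: float
    called_fraction_negative: float

    @property
    def confusion(self) -> np.ndarray:
        """2x2 counts [[tp, fn], [fp, tn]] (rows: true class)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SingleXResult:
    proportion: float
    n_single_x: int
    n_called: int
    ci_low: float
    ci_high: float
    confidence: float = 0.95


@dataclass(frozen=True)
class FamilyReport:
    family_id: str
    n_offspring_called: int
    n_single_x: int
    n_xx: int
    ratio_x_to_xx: float         # NaN when no XX offspring called
    inferred_mother: str
    small_sample: bool = False   # XX verdict from a brood below the minimum


def _merged(assignments, annotations) -> pd.DataFrame:
    a = assignments_frame(assignments)
    b = annotations_frame(annotations)
    return a.merge(b, on="sample_id", how="left", validate="one_to_one")


def performance(
    assignments: Iterable[SexAssignment] | pd.DataFrame,
    annotations: Iterable[SampleAnnotation] | pd.DataFrame,
    positive_class: str = "male",
) -> PerformanceReport:
    """Score determinate consensus calls against known phenotypic sex.

    Sensitivity is the fraction of phenotype-positive samples (among those
    called) assigned to the positive class; specificity the fraction of
    phenotype-negative samples assigned to the negative class.  Samples
    removed by the pipeline are excluded from the 2x2 and reported via
    ``n_removed`` and the per-class called fractions.
    """
    if positive_class not in ("male", "female"):
        raise ValueError("positive_class must be 'male' or 'female'")
    merged = _merged(assignments, annotations)
    evaluable = merged[merged["phenotypic_sex"].isin(["male", "female"])]
    if evaluable.empty:
        raise ValueError("no evaluable samples (known phenotype required)")

    called = evaluable[evaluable["consensus"].isin(_CONSENSUS_TO_SEX)]
    predicted = called["consensus"].map(_CONSENSUS_TO_SEX)
    truth = called["phenotypic_sex"]

    pos, neg = positive_class, ("female" if positive_class == "male" else "male")
    tp = int(((truth == pos) & (predicted == pos)).sum())
    fn = int(((truth == pos) & (predicted == neg)).sum())
    fp = int(((truth == neg) & (predicted == pos)).sum())
    tn = int(((truth == neg) & (predicted == neg)).sum())

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    n_pos_all = int((evaluable["phenotypic_sex"] == pos).sum())
    n_neg_all = int((evaluable["phenotypic_sex"] == neg).sum())
    return PerformanceReport(
        positive_class=positive_class,
        n_called=len(called),
        n_removed=len(evaluable) - len(called),
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        called_fraction_positive=_ratio(tp + fn, n_pos_all),
        called_fraction_negative=_ratio(tn + fp, n_neg_all),
    )


def performance_both(assignments, annotations) -> dict[str, PerformanceReport]:
    """Reports with each sex as the positive class (no hidden convention)."""
    return {
        cls: performance(assignments, annotations, cls)
        for cls in ("male", "female")
    }


def filter_bias_test(
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    correction: str = "yates",
) -> ChiSquareResult:
    """Chi-squared test for unequal QC-failure rates between two groups.

    Each group is ``(n_failed, n_passed)``.  ``correction`` is ``"yates"``
    (default, matching R's 2x2 default) or ``"none"``.
    """
    if correction not in ("yates", "none"):
        raise ValueError("correction must be 'yates' or 'none'")
    table = np.array([group_a, group_b], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-squared test undefined: a table margin is zero")
    stat, p, df, _ = stats.chi2_contingency(table, correction=(correction == "yates"))
    return ChiSquareResult(float(stat), int(df), float(p))


def single_x_proportion(
    assignments: Iterable[SexAssignment] | pd.DataFrame,
    annotations: Iterable[SampleAnnotation] | pd.DataFrame,
    haplotypes: Iterable[str] = ("HT1", "HT1*"),
    stage: str = "adult",
    confidence: float = 0.95,
) -> SingleXResult:
    """Fraction of single-X genotypes among called samples in a stratum.

    Only adults are used by default: an XX mother can only produce XX
    offspring, so including broods would underrepresent single-X genotypes.
    Removed samples are excluded from the denominator.  The CI is exact
    Clopper-Pearson.
    """
    merged = _merged(assignments, annotations)
    sel = merged[merged["haplotype"].isin(set(haplotypes))]
    if stage != "all":
        sel = sel[sel["stage"] == stage]
    called = sel[sel["consensus"].isin(_CONSENSUS_TO_SEX)]
    if called.empty:
        raise ValueError("no called samples in the selected stratum")
    k = int((called["consensus"] == CONSENSUS_MALE).sum())
    n = len(called)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence,
                                             method="exact")
    return SingleXResult(k / n, k, n, float(ci.low), float(ci.high), confidence)


def family_ratios(
    assignments: Iterable[SexAssignment] | pd.DataFrame,
    annotations: Iterable[SampleAnnotation] | pd.DataFrame,
    min_confident_n: int = 5,
) -> list[FamilyReport]:
    """Genotype counts and inferred maternal genotype per family.

    A family with both genotypes among called offspring implies a single-X
    mother (an XX mother cannot produce single-X daughters under
    gynogenesis); an all-XX family implies an XX mother, flagged
    ``small_sample`` when fewer than ``min_confident_n`` offspring were
    called; fewer than 2 called offspring is indeterminate.
    """
    merged = _merged(assignments, annotations)
    merged = merged[merged["family_id"].notna()]
    reports = []
    for family_id, sub in merged.groupby("family_id", sort=True):
        called = sub[sub["consensus"].isin(_CONSENSUS_TO_SEX)]
        n_single = int((called["consensus"] == CONSENSUS_MALE).sum())
        n_xx = int((called["consensus"] == CONSENSUS_FEMALE).sum())
        n_called = n_single + n_xx
        ratio = n_single / n_xx if n_xx > 0 else float("nan")
        if n_called < 2:
            mother = MOTHER_INDETERMINATE
            small = False
        elif n_single > 0:
            mother = MOTHER_SINGLE_X
            small = False
        else:
            mother = MOTHER_XX
            small = n_called < min_confident_n
        reports.append(
            FamilyReport(
                str(family_id), n_called, n_single, n_xx, ratio, mother, small
            )
        )
    return reports


def family_frame(reports: Iterable[FamilyReport]) -> pd.DataFrame:
    reports = list(reports)
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in reports],
            "n_offspring_called": [r.n_offspring_called for r in reports],
            "n_single_x": [r.n_single_x for r in reports],
            "n_xx": [r.n_xx for r in reports],
            "ratio_x_to_xx": [r.ratio_x_to_xx for r in reports],
            "inferred_mother": [r.inferred_mother for r in reports],
            "small_sample": [r.small_sample for r in reports],
        }
    )
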