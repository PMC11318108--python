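"""Cohort statistics: performance, filter bias, proportions, family ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from xdosage import (
    family_ratios,
    filter_bias_test,
    performance,
    performance_both,
    single_x_proportion,
)
from xdosage.cohort import MOTHER_INDETERMINATE, MOTHER_SINGLE_X, MOTHER_XX


def tables(rows):
    """rows: (sample_id, consensus, phenotypic_sex, haplotype, stage, family)."""
    assignments = pd.DataFrame(
        {
            "sample_id": [r[0] for r in rows],
            "consensus": [r[1] for r in rows],
            "removal_reason": None,
            "mean_fold": np.nan,
            "marker_sd": np.nan,
        }
    )
    annotations = pd.DataFrame(
        {
            "sample_id": [r[0] for r in rows],
            "phenotypic_sex": [r[2] for r in rows],
            "haplotype": [r[3] if len(r) > 3 else "HT2" for r in rows],
            "stage": [r[4] if len(r) > 4 else "adult" for r in rows],
            "family_id": [r[5] if len(r) > 5 else None for r in rows],
        }
    )
    return assignments, annotations


def cohort(n_tp=0, n_fn=0, n_fp=0, n_tn=0, n_removed_male=0, n_removed_female=0):
    rows = []
    for i in range(n_tp):
        rows.append((f"tp{i}", "male_singleX", "male"))
    for i in range(n_fn):
        rows.append((f"fn{i}", "female_XX", "male"))
    for i in range(n_fp):
        rows.append((f"fp{i}", "male_singleX", "female"))
    for i in range(n_tn):
        rows.append((f"tn{i}", "female_XX", "female"))
    for i in range(n_removed_male):
        rows.append((f"rm{i}", "removed", "male"))
    for i in range(n_removed_female):
        rows.append((f"rf{i}", "removed", "female"))
    return tables(rows)


class TestPerformance:
    def test_perfect_concordance(self):
        report = performance(*cohort(n_tp=5, n_tn=5))
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.n_called == 10

    def test_constructed_confusion_matrix(self):
        report = performance(*cohort(n_tp=9, n_fn=1, n_fp=0, n_tn=10))
        assert report.sensitivity == pytest.approx(0.9)
        assert report.specificity == pytest.approx(1.0)
        assert report.confusion.tolist() == [[9, 1], [0, 10]]

    def test_removed_samples_counted_separately(self):
        report = performance(*cohort(n_tp=12, n_tn=17, n_removed_male=1))
        assert report.n_removed == 1
        assert report.sensitivity == 1.0
        # the strictness cost shows up in the called fraction instead
        assert report.called_fraction_positive == pytest.approx(12 / 13)

    def test_both_class_reports(self):
        reports = performance_both(*cohort(n_tp=9, n_fn=1, n_tn=10))
        assert reports["male"].sensitivity == pytest.approx(0.9)
        # with female positive, the roles of the error rates swap
        assert reports["female"].sensitivity == pytest.approx(1.0)
        assert reports["female"].specificity == pytest.approx(0.9)

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        sexes = ["male"] * 100 + ["female"] * 100
        calls = ["male_singleX"] * 100 + ["female_XX"] * 100
        rng.shuffle(sexes)
        rows = [(f"s{i}", calls[i], sexes[i]) for i in range(200)]
        report = performance(*tables(rows))
        assert 0.35 < report.sensitivity < 0.65
        assert 0.35 < report.specificity < 0.65

    def test_no_evaluable_samples_rejected(self):
        with pytest.raises(ValueError, match="evaluable"):
            performance(*tables([("s1", "female_XX", "unknown")]))


class TestFilterBiasTest:
    def test_identical_proportions_give_zero(self):
        result = filter_bias_test((10, 10), (10, 10))
        assert result.statistic == 0.0
        assert result.df == 1
        assert result.p_value == 1.0

    def test_uncorrected_matches_closed_form(self):
        # Pearson on [[1, 9], [5, 5]]: n(ad-bc)^2 / (row1 row2 col1 col2)
        expected = 20 * (1 * 5 - 9 * 5) ** 2 / (10 * 10 * 6 * 14)
        result = filter_bias_test((1, 9), (5, 5), correction="none")
        assert result.statistic == pytest.approx(expected)

    @pytest.mark.parametrize("a,b", [((1, 9), (5, 5)), ((3, 17), (8, 12))])
    def test_yates_never_exceeds_uncorrected(self, a, b):
        yates = filter_bias_test(a, b, correction="yates")
        none = filter_bias_test(a, b, correction="none")
        assert yates.statistic <= none.statistic

    def test_symmetric_under_group_swap(self):
        r1 = filter_bias_test((1, 9), (5, 5))
        r2 = filter_bias_test((5, 5), (1, 9))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            filter_bias_test((0, 10), (0, 10))


class TestSingleXProportion:
    def _stratum(self, n_single, n_total, haplotype="HT1"):
        rows = []
        for i in range(n_single):
            rows.append((f"x{i}", "male_singleX", "female", haplotype, "adult"))
        for i in range(n_total - n_single):
            rows.append((f"f{i}", "female_XX", "female", haplotype, "adult"))
        return tables(rows)

    def test_two_of_eleven(self):
        result = single_x_proportion(*self._stratum(2, 11), haplotypes=["HT1"])
        assert round(100 * result.proportion, 1) == 18.2
        assert result.ci_low < 0.182 < result.ci_high

    def test_three_of_fourteen(self):
        result = single_x_proportion(*self._stratum(3, 14, "HT1*"))
        assert round(100 * result.proportion, 1) == 21.4

    def test_none_of_ten(self):
        result = single_x_proportion(*self._stratum(0, 10))
        assert result.proportion == 0.0
        assert result.ci_low == 0.0

    def test_larvae_excluded_by_default(self):
        rows = [
            ("a1", "male_singleX", "female", "HT1", "adult"),
            ("a2", "female_XX", "female", "HT1", "adult"),
            ("l1", "male_singleX", "female", "HT1", "larva"),
        ]
        result = single_x_proportion(*tables(rows))
        assert result.n_called == 2
        result_all = single_x_proportion(*tables(rows), stage="all")
        assert result_all.n_called == 3

    def test_removed_samples_not_in_denominator(self):
        rows = [
            ("a1", "male_singleX", "female", "HT1", "adult"),
            ("a2", "female_XX", "female", "HT1", "adult"),
            ("a3", "removed", "female", "HT1", "adult"),
        ]
        result = single_x_proportion(*tables(rows))
        assert result.n_called == 2

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            single_x_proportion(*self._stratum(1, 5), haplotypes=["HT3"])


class TestFamilyRatios:
    def _family(self, family_id, n_xx, n_single, n_removed=0):
        rows = []
        for i in range(n_xx):
            rows.append((f"{family_id}x{i}", "female_XX", "female", "HT1",
                         "larva", family_id))
        for i in range(n_single):
            rows.append((f"{family_id}s{i}", "male_singleX", "female", "HT1",
                         "larva", family_id))
        for i in range(n_removed):
            rows.append((f"{family_id}r{i}", "removed", "female", "HT1",
                         "larva", family_id))
        return rows

    def test_mixed_family_implies_single_x_mother(self):
        (report,) = family_ratios(*tables(self._family("F1", 8, 2)))
        assert report.ratio_x_to_xx == pytest.approx(0.25)
        assert report.inferred_mother == MOTHER_SINGLE_X

    def test_all_xx_family_implies_xx_mother(self):
        (report,) = family_ratios(*tables(self._family("F2", 11, 0)))
        assert report.inferred_mother == MOTHER_XX
        assert report.ratio_x_to_xx == 0.0
        assert not report.small_sample

    def test_small_all_xx_family_flagged(self):
        (report,) = family_ratios(*tables(self._family("F3", 3, 0)))
        assert report.inferred_mother == MOTHER_XX
        assert report.small_sample

    def test_single_called_offspring_indeterminate(self):
        (report,) = family_ratios(*tables(self._family("F4", 1, 0, n_removed=3)))
        assert report.inferred_mother == MOTHER_INDETERMINATE
        assert report.n_offspring_called == 1

    def test_families_sorted_and_counted(self):
        rows = self._family("F1", 4, 1) + self._family("F2", 5, 0)
        reports = family_ratios(*tables(rows))
        assert [r.family_id for r in reports] == ["F1", "F2"]
        assert [r.n_offspring_called for r in reports] == [5, 5]
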