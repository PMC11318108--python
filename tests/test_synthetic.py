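"""Generator: log-linear Ct model, dilution series, families, crosses."""

import math

import numpy as np
import pandas as pd
import pytest

from xdosage import (
    SampleTruth,
    cohort_truths,
    simulate_cross_genotypes,
    simulate_family,
    simulate_plate,
    simulate_standard_curve,
)
from xdosage.synthetic import GENOTYPE_SINGLE_X, GENOTYPE_XX

from conftest import make_config


class TestSimulatePlate:
    def test_noise_free_two_copy_ct_equals_baseline(self, doubling_config):
        truths = [SampleTruth("F1", GENOTYPE_XX, phenotypic_sex="female")]
        plate, _ = simulate_plate(doubling_config, truths, "F1")
        for marker in doubling_config.markers:
            wells = plate.wells[plate.wells["target"] == marker.name]
            assert (wells["ct"] == marker.baseline_ct).all()

    def test_noise_free_single_x_is_one_cycle_later(self, doubling_config):
        """Half the template needs exactly one extra doubling when A = 2."""
        truths = [
            SampleTruth("F1", GENOTYPE_XX, phenotypic_sex="female"),
            SampleTruth("M1", GENOTYPE_SINGLE_X, phenotypic_sex="male"),
        ]
        plate, _ = simulate_plate(doubling_config, truths, "F1")
        male = plate.wells[plate.wells["sample_id"] == "M1"]
        for marker in doubling_config.markers:
            ct = male.loc[male["target"] == marker.name, "ct"]
            expected = marker.baseline_ct + (1.0 if marker.role == "x_linked" else 0.0)
            assert (ct == expected).all()

    def test_replicate_noise_magnitude(self):
        """Monte-Carlo: per-well noise SD is recovered from many replicates."""
        config = make_config(rep_noise_sd=0.1, n_replicates=1000, seed=7)
        plate, _ = simulate_plate(
            config, [SampleTruth("F1", GENOTYPE_XX)], "F1"
        )
        ct = plate.wells[plate.wells["target"] == "VSSC"]["ct"]
        assert ct.std(ddof=1) == pytest.approx(0.1, abs=0.01)

    def test_sample_offset_shifts_all_wells_equally(self):
        base = make_config(seed=3)
        shifted = make_config(sample_offset_sd=2.0, seed=3)
        truths = [
            SampleTruth("F1", GENOTYPE_XX),
            SampleTruth("M1", GENOTYPE_SINGLE_X),
        ]
        p0, _ = simulate_plate(base, truths, "F1")
        p1, _ = simulate_plate(shifted, truths, "F1")
        delta = p1.wells["ct"] - p0.wells["ct"]
        per_sample = pd.DataFrame(
            {"sample_id": p1.wells["sample_id"], "delta": delta}
        ).groupby("sample_id")["delta"]
        assert (per_sample.agg(lambda d: d.max() - d.min()) < 1e-9).all()
        assert per_sample.mean().abs().max() > 0.0  # offsets actually applied

    def test_same_seed_bit_identical(self):
        config = make_config(
            rep_noise_sd=0.2, sample_offset_sd=0.3, outlier_prob=0.1, seed=42
        )
        truths = cohort_truths(3, 3)
        p0, t0 = simulate_plate(config, truths, "SF001")
        p1, t1 = simulate_plate(config, truths, "SF001")
        pd.testing.assert_frame_equal(p0.wells, p1.wells)
        pd.testing.assert_frame_equal(t0, t1)

    def test_outliers_only_shift_upward(self):
        config = make_config(outlier_prob=0.5, seed=5)
        plate, _ = simulate_plate(config, [SampleTruth("F1", GENOTYPE_XX)], "F1")
        baselines = {m.name: m.baseline_ct for m in config.markers}
        expected = plate.wells["target"].map(baselines)
        assert (plate.wells["ct"] >= expected - 1e-12).all()
        assert (plate.wells["ct"] > expected + 1).any()

    def test_reference_must_be_xx(self, doubling_config):
        truths = [SampleTruth("M1", GENOTYPE_SINGLE_X)]
        with pytest.raises(ValueError, match="XX"):
            simulate_plate(doubling_config, truths, "M1")

    def test_empty_truths_rejected(self, doubling_config):
        with pytest.raises(ValueError, match="empty"):
            simulate_plate(doubling_config, [], "F1")


class TestStandardCurveSimulation:
    def test_tenfold_spacing_under_perfect_doubling(self):
        curve = simulate_standard_curve(2.0, baseline_ct=20.0)
        spacing = np.diff(curve["ct"])
        assert spacing == pytest.approx(math.log2(10), abs=1e-9)

    def test_default_dilution_series_concentrations(self):
        curve = simulate_standard_curve(2.0, baseline_ct=20.0, n_steps=6)
        assert curve["concentration"].tolist() == pytest.approx(
            [50, 5, 0.5, 0.05, 0.005, 0.0005]
        )

    def test_undiluted_point_at_baseline(self):
        curve = simulate_standard_curve(2.0, baseline_ct=20.0)
        assert curve["ct"].iloc[0] == 20.0

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="2 dilution points"):
            simulate_standard_curve(2.0, baseline_ct=20.0, n_steps=1)


class TestSimulateFamily:
    def test_xx_mother_gives_only_xx(self):
        offspring = simulate_family(GENOTYPE_XX, 11, single_x_ratio=0.9, seed=1)
        assert len(offspring) == 11
        assert all(o.genotype == GENOTYPE_XX for o in offspring)
        assert all(o.phenotypic_sex == "female" for o in offspring)
        assert len({o.family_id for o in offspring}) == 1

    def test_zero_ratio_degenerates_to_all_xx(self):
        offspring = simulate_family(GENOTYPE_SINGLE_X, 20, single_x_ratio=0.0, seed=1)
        assert all(o.genotype == GENOTYPE_XX for o in offspring)

    def test_single_x_fraction_matches_ratio(self):
        offspring = simulate_family(
            GENOTYPE_SINGLE_X, 10_000, single_x_ratio=0.25, seed=2
        )
        frac = sum(o.genotype == GENOTYPE_SINGLE_X for o in offspring) / 10_000
        assert frac == pytest.approx(0.25, abs=0.01)


class TestSimulateCross:
    def test_x_linked_mendelian_pattern(self):
        table, truth = simulate_cross_genotypes(
            20, fraction_x=1.0, error_rate=0.0, seed=0
        )
        assert (truth["category"] == "x_linked").all()
        for _, sub in table.groupby("contig"):
            father = sub[sub["role"] == "father"].iloc[0]
            assert pd.isna(father["allele2"])  # hemizygous
            daughters = sub[(sub["role"] == "offspring") & (sub["sex"] == "female")]
            sons = sub[(sub["role"] == "offspring") & (sub["sex"] == "male")]
            assert (
                (daughters["allele1"] == father["allele1"])
                | (daughters["allele2"] == father["allele1"])
            ).all()
            assert (sons["allele1"] != father["allele1"]).all()
            assert sons["allele2"].isna().all()

    def test_autosomal_biparental_inheritance(self):
        table, truth = simulate_cross_genotypes(
            20, fraction_x=0.0, fraction_y=0.0, error_rate=0.0, seed=1
        )
        assert (truth["category"] == "autosomal").all()
        for _, sub in table.groupby("contig"):
            father = sub[sub["role"] == "father"].iloc[0]
            mother = sub[sub["role"] == "mother"].iloc[0]
            pat = {father["allele1"], father["allele2"]} - {None, np.nan}
            mat = {mother["allele1"], mother["allele2"]} - {None, np.nan}
            for _, off in sub[sub["role"] == "offspring"].iterrows():
                alleles = {a for a in (off["allele1"], off["allele2"]) if pd.notna(a)}
                assert alleles & {p for p in pat if pd.notna(p)}
                assert alleles & {m for m in mat if pd.notna(m)}

    def test_degenerate_fractions_give_only_autosomal(self):
        _, truth = simulate_cross_genotypes(10, fraction_x=0, fraction_y=0, seed=0)
        assert set(truth["category"]) == {"autosomal"}

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_cross_genotypes(10, fraction_x=0.8, fraction_y=0.5)
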