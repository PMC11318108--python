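"""Synthetic data generation for the copy-number sexing pipeline.

Everything downstream of the instrument can be exercised without real data:

* :func:`simulate_plate` draws triplicate Ct values from a log-linear
  amplification model.  A sample with true copy number ``c`` at marker ``m``
  (2 for autosomes and XX at X markers, 1 for single-X at X markers) yields

      Ct = B_m - log_{A_m}(c/2 * input_scale) + delta_s + eps

  where ``B_m`` is the marker's baseline Ct at the standard 5 ng input,
  ``A_m`` its per-cycle amplification factor, ``delta_s`` a sample-level
  offset shared by all wells of the sample (pipetting/DNA-quality effects,
  cancelled by the within-sample dCt), and ``eps`` independent replicate
  noise.  Sporadic late-amplification outliers add a fixed upward Ct shift.

* :func:`simulate_standard_curve` produces the serial-dilution series used
  to estimate amplification factors (default 50 ng/uL down in 1:10 steps).

* :func:`simulate_family` generates gynogenetic broods: XX mothers give
  all-XX offspring; single-X mothers give single-X offspring at a set rate.

* :func:`simulate_cross_genotypes` builds a one-family genotype table
  (mother, father, sexed offspring) with X-linked, Y-linked and autosomal
  loci segregating by Mendelian rules, for the segregation classifier.

All generators are reproducible from an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import AUTOSOMAL, X_LINKED, Marker, MarkerPanel
from .plate_io import PLATE_COLUMNS, PlateData

GENOTYPE_XX = "XX"
GENOTYPE_SINGLE_X = "singleX"
GENOTYPES = (GENOTYPE_XX, GENOTYPE_SINGLE_X)


@dataclass(frozen=True)
class SimMarker:
    """A marker as the generator sees it: role, true amplification factor,
    and baseline Ct of a two-copy sample at standard input."""

    name: str
    role: str
    amplification_factor: float = 2.0
    baseline_ct: float = 24.0

    def __post_init__(self) -> None:
        Marker(self.name, self.role, self.amplification_factor)  # reuse checks
        if self.baseline_ct <= 0:
            raise ValueError(f"marker {self.name!r}: baseline_ct must be positive")


def default_sim_markers() -> tuple[SimMarker, ...]:
    """Default panel: baselines 23.5-24.4 cycles put two-copy samples well
    below the 26.5 QC cutoff while +4-cycle outliers land clearly above it."""
    return (
        SimMarker("VSSC", X_LINKED, 1.96, 24.0),
        SimMarker("SL4108", X_LINKED, 1.91, 24.4),
        SimMarker("SL3442", X_LINKED, 1.94, 23.8),
        SimMarker("AL40057", AUTOSOMAL, 1.98, 23.5),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the validation-study conditions."""

    markers: tuple[SimMarker, ...] = field(default_factory=default_sim_markers)
    rep_noise_sd: float = 0.15       # cycles, independent per well
    sample_offset_sd: float = 0.2    # cycles, shared across a sample's wells
    outlier_prob: float = 0.05       # per well
    outlier_shift: float = 4.0       # cycles, always upward
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if self.rep_noise_sd < 0 or self.sample_offset_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.outlier_prob < 1:
            raise ValueError("outlier_prob must be in [0, 1)")
        if self.outlier_shift <= 0:
            raise ValueError("outlier_shift must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.panel()  # role/count/factor invariants

    def panel(self) -> MarkerPanel:
        return MarkerPanel(
            tuple(Marker(m.name, m.role, m.amplification_factor) for m in self.markers)
        )


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated individual."""

    sample_id: str
    genotype: str                       # XX | singleX
    haplotype: str = "HT2"
    stage: str = "adult"
    phenotypic_sex: str = "unknown"
    family_id: str | None = None
    input_scale: float = 1.0            # DNA-input multiplier (1 = on-spec 5 ng)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")

    def copy_number(self, role: str) -> int:
        """True template copy number at a marker of the given role."""
        if role == AUTOSOMAL:
            return 2
        return 2 if self.genotype == GENOTYPE_XX else 1


def truth_frame(truths: Iterable[SampleTruth]) -> pd.DataFrame:
    truths = list(truths)
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "genotype": [t.genotype for t in truths],
            "haplotype": [t.haplotype for t in truths],
            "stage": [t.stage for t in truths],
            "phenotypic_sex": [t.phenotypic_sex for t in truths],
            "family_id": [t.family_id for t in truths],
            "input_scale": [t.input_scale for t in truths],
        }
    )


def simulate_plate(
    config: SynthConfig,
    truths: Sequence[SampleTruth],
    reference_sample: str,
    plate_id: str = "P1",
) -> tuple[PlateData, pd.DataFrame]:
    """Simulate one plate of triplicate Ct values for the given samples.

    Returns the plate and a truth table (one row per sample).  The reference
    sample must be among ``truths`` and have an XX genotype — the analysis
    anchors fold changes on a known two-X female.
    """
    truths = list(truths)
    if not truths:
        raise ValueError("truth list is empty")
    by_id = {t.sample_id: t for t in truths}
    if len(by_id) != len(truths):
        raise ValueError("duplicate sample ids in truths")
    if reference_sample not in by_id:
        raise ValueError(f"reference sample {reference_sample!r} not among truths")
    if by_id[reference_sample].genotype != GENOTYPE_XX:
        raise ValueError(
            f"reference sample {reference_sample!r} must have genotype XX"
        )

    rng = np.random.default_rng(config.seed)
    offsets = {
        t.sample_id: rng.normal(0.0, config.sample_offset_sd)
        if config.sample_offset_sd > 0
        else 0.0
        for t in truths
    }

    rows: list[tuple] = []
    well_no = 0
    for t in truths:
        for m in config.markers:
            log_a = math.log(m.amplification_factor)
            true_ct = m.baseline_ct - math.log(
                t.copy_number(m.role) / 2.0 * t.input_scale
            ) / log_a
            for rep in range(1, config.n_replicates + 1):
                well_no += 1
                ct = true_ct + offsets[t.sample_id]
                if config.rep_noise_sd > 0:
                    ct += rng.normal(0.0, config.rep_noise_sd)
                if config.outlier_prob > 0 and rng.random() < config.outlier_prob:
                    ct += config.outlier_shift
                rows.append(
                    (plate_id, f"w{well_no:04d}", t.sample_id, m.name, rep, ct)
                )

    wells = pd.DataFrame(rows, columns=list(PLATE_COLUMNS))
    return PlateData(plate_id, wells, reference_sample), truth_frame(truths)


def simulate_standard_curve(
    a_true: float,
    baseline_ct: float,
    n_steps: int = 6,
    step: float = 10.0,
    top_concentration: float = 50.0,
    rep_noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Serial-dilution standard curve: Ct rises by ``log_A(step)`` per step.

    Defaults reproduce the 50 ng/uL .. 0.5 pg/uL 1:10 series (6 points).
    Noise-free unless ``rep_noise_sd > 0``.
    """
    if not 1.0 < a_true <= 2.0:
        raise ValueError("a_true must be in (1, 2]")
    if n_steps < 2:
        raise ValueError("need at least 2 dilution points to estimate a slope")
    if step <= 1:
        raise ValueError("step must be a dilution factor > 1")
    rng = np.random.default_rng(seed)
    spacing = math.log(step) / math.log(a_true)
    rows = []
    for k in range(n_steps):
        conc = top_concentration * step ** (-k)
        ct0 = baseline_ct + k * spacing
        for rep in range(1, n_replicates + 1):
            ct = ct0 + (rng.normal(0.0, rep_noise_sd) if rep_noise_sd > 0 else 0.0)
            rows.append((conc, rep, ct))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "ct"])


def simulate_family(
    mother_genotype: str,
    n_offspring: int,
    single_x_ratio: float = 0.25,
    seed: int = 0,
    family_id: str = "F1",
    haplotype: str = "HT1",
    stage: str = "larva",
) -> list[SampleTruth]:
    """One gynogenetic brood.  XX mothers produce only XX offspring; single-X
    mothers produce single-X offspring independently at ``single_x_ratio``.
    All offspring are phenotypically female (the feminized-haplotype case)."""
    if mother_genotype not in GENOTYPES:
        raise ValueError(f"mother_genotype must be one of {GENOTYPES}")
    if not 0.0 <= single_x_ratio <= 1.0:
        raise ValueError("single_x_ratio must be in [0, 1]")
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    offspring = []
    for i in range(1, n_offspring + 1):
        if mother_genotype == GENOTYPE_SINGLE_X and rng.random() < single_x_ratio:
            genotype = GENOTYPE_SINGLE_X
        else:
            genotype = GENOTYPE_XX
        offspring.append(
            SampleTruth(
                sample_id=f"{family_id}-o{i:03d}",
                genotype=genotype,
                haplotype=haplotype,
                stage=stage,
                phenotypic_sex="female",
                family_id=family_id,
            )
        )
    return offspring


def cohort_truths(
    n_xx: int,
    n_single_x: int,
    haplotype: str = "HT2",
    stage: str = "adult",
    prefix: str = "S",
    concordant_phenotype: bool = True,
) -> list[SampleTruth]:
    """Convenience cohort builder: XX then single-X samples, with phenotypic
    sex matching genotype when ``concordant_phenotype`` (the normally
    reproducing validation case)."""
    truths = []
    for i in range(1, n_xx + 1):
        truths.append(
            SampleTruth(
                f"{prefix}F{i:03d}",
                GENOTYPE_XX,
                haplotype=haplotype,
                stage=stage,
                phenotypic_sex="female" if concordant_phenotype else "unknown",
            )
        )
    for i in range(1, n_single_x + 1):
        truths.append(
            SampleTruth(
                f"{prefix}M{i:03d}",
                GENOTYPE_SINGLE_X,
                haplotype=haplotype,
                stage=stage,
                phenotypic_sex="male" if concordant_phenotype else "unknown",
            )
        )
    return truths


# ---------------------------------------------------------------------------
# Family cross genotypes for the segregation classifier
# ---------------------------------------------------------------------------

CATEGORY_X = "x_linked"
CATEGORY_Y = "y_linked"
CATEGORY_AUTOSOMAL = "autosomal"
CATEGORY_UNINFORMATIVE = "uninformative"

_CROSS_COLUMNS = ("contig", "individual", "role", "sex", "allele1", "allele2")


def _genotype_row(contig, individual, role, sex, alleles):
    a = sorted(alleles) if alleles else []
    return (
        contig,
        individual,
        role,
        sex,
        a[0] if len(a) >= 1 else None,
        a[1] if len(a) >= 2 else None,
    )


def simulate_cross_genotypes(
    n_contigs: int,
    fraction_x: float = 0.1,
    fraction_y: float = 0.0,
    n_sons: int = 6,
    n_daughters: int = 4,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype table for one cross (mother, father, sexed offspring).

    X-linked contigs: the father is hemizygous for a private allele that
    reaches all daughters and no sons; sons are hemizygous for one maternal
    allele.  Y-linked contigs: only father and sons carry the locus.
    Autosomal contigs: ordinary biparental inheritance.  Each recorded
    genotype is independently corrupted with probability ``error_rate``
    (replaced by a random genotype over the contig's allele universe plus a
    spurious allele), emulating genotyping error.

    Returns the long table (contig, individual, role, sex, allele1, allele2)
    and a truth table (contig, category).
    """
    if n_contigs < 1 or n_sons < 1 or n_daughters < 1:
        raise ValueError("counts must be >= 1")
    if fraction_x < 0 or fraction_y < 0 or fraction_x + fraction_y > 1:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    n_x = int(round(n_contigs * fraction_x))
    n_y = int(round(n_contigs * fraction_y))
    categories = (
        [CATEGORY_X] * n_x
        + [CATEGORY_Y] * n_y
        + [CATEGORY_AUTOSOMAL] * (n_contigs - n_x - n_y)
    )
    sons = [f"son{i}" for i in range(1, n_sons + 1)]
    daughters = [f"dau{i}" for i in range(1, n_daughters + 1)]

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for idx, cat in enumerate(categories, start=1):
        contig = f"contig{idx:05d}"
        genotypes: dict[str, tuple[str, str, set[str] | None]] = {}
        if cat == CATEGORY_X:
            mother = {"b", "c"} if rng.random() < 0.5 else {"b"}
            genotypes["father"] = ("father", "male", {"a"})
            genotypes["mother"] = ("mother", "female", set(mother))
            for d in daughters:
                genotypes[d] = ("offspring", "female", {"a", rng.choice(sorted(mother))})
            for s in sons:
                genotypes[s] = ("offspring", "male", {rng.choice(sorted(mother))})
        elif cat == CATEGORY_Y:
            genotypes["father"] = ("father", "male", {"a"})
            genotypes["mother"] = ("mother", "female", None)
            for d in daughters:
                genotypes[d] = ("offspring", "female", None)
            for s in sons:
                genotypes[s] = ("offspring", "male", {"a"})
        else:
            father = {rng.choice(["a", "b"]), rng.choice(["a", "b"])}
            mother = {rng.choice(["c", "d"]), rng.choice(["c", "d"])}
            genotypes["father"] = ("father", "male", set(father))
            genotypes["mother"] = ("mother", "female", set(mother))
            for o in daughters + sons:
                sex = "female" if o.startswith("dau") else "male"
                genotypes[o] = (
                    "offspring",
                    sex,
                    {rng.choice(sorted(father)), rng.choice(sorted(mother))},
                )

        universe = sorted(
            set().union(*(g for _, _, g in genotypes.values() if g)) | {"e"}
        )
        for individual, (role, sex, alleles) in genotypes.items():
            if alleles is not None and error_rate > 0 and rng.random() < error_rate:
                k = int(rng.integers(1, 3))
                alleles = set(rng.choice(universe, size=k, replace=True).tolist())
            rows.append(_genotype_row(contig, individual, role, sex, alleles))
        truth_rows.append((contig, cat))

    table = pd.DataFrame(rows, columns=list(_CROSS_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=["contig", "category"])
    return table, truth
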