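"""Rule-based Mendelian segregation classifier for sex-linkage.

Given genotypes of one family (mother, father, sexed offspring) at many
loci, each locus is assigned to one of four categories by deterministic
inheritance rules:

* ``x_linked`` — the father shows a single allele (hemizygous, though
  homozygous-looking calls are accepted: sequence data cannot separate the
  two) which appears in every daughter and in no son, and sons are
  hemizygous for a maternal allele;
* ``y_linked`` — a paternal allele absent from the mother appears in every
  son and no daughter (mother and daughters may lack the locus entirely);
* ``autosomal`` — every offspring genotype is explainable as one allele
  from each parent, in both sexes;
* ``uninformative`` — anything else: missing parents, monomorphic loci, too
  few scorable offspring, or more rule violations than the tolerance
  allows.

This is a deliberately simple, fully deterministic classifier for
demonstrating and testing the discovery logic on family crosses; it is not
a reimplementation of probabilistic segregation models, which additionally
handle genotyping uncertainty through posterior probabilities.

Genotypes are unphased, unordered allele sets of size one (hemizygous or
homozygous) or two, or missing.  Classification is invariant to allele
names and offspring order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

CATEGORY_X = "x_linked"
CATEGORY_Y = "y_linked"
CATEGORY_AUTOSOMAL = "autosomal"
CATEGORY_UNINFORMATIVE = "uninformative"
CATEGORIES = (CATEGORY_X, CATEGORY_Y, CATEGORY_AUTOSOMAL, CATEGORY_UNINFORMATIVE)

Genotype = frozenset  # of allele strings; None = locus missing/untyped


@dataclass(frozen=True)
class SegParams:
    """Classifier tolerances."""

    max_violation_rate: float = 0.0      # fraction of scored offspring
    min_informative_offspring: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_violation_rate < 0.5:
            raise ValueError("max_violation_rate must be in [0, 0.5)")
        if self.min_informative_offspring < 1:
            raise ValueError("min_informative_offspring must be >= 1")


def parse_genotype(allele1: object, allele2: object = None) -> Genotype | None:
    """Two allele cells -> unordered genotype set (None when untyped)."""

    def _clean(value: object) -> str | None:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        text = str(value).strip()
        return text or None

    a1, a2 = _clean(allele1), _clean(allele2)
    if a1 is None and a2 is not None:
        raise ValueError(f"allele2 {a2!r} given without allele1")
    if a1 is None:
        return None
    return frozenset({a1} if a2 is None else {a1, a2})


def classify_contig(
    father: Genotype | None,
    mother: Genotype | None,
    offspring: Sequence[tuple[str, Genotype | None]],
    params: SegParams = SegParams(),
) -> str:
    """Classify one locus from parental and sexed offspring genotypes.

    ``offspring`` is a sequence of ``(sex, genotype)`` with sex ``"male"``
    or ``"female"``.  Checks are tried in the order X, Y, autosomal; the
    first pattern whose violations stay within ``max_violation_rate`` of
    scored (non-missing) offspring wins.
    """
    scored = [(sex, g) for sex, g in offspring if g]
    n = len(scored)
    if n < params.min_informative_offspring:
        return CATEGORY_UNINFORMATIVE

    typed = [g for g in (father, mother) if g] + [g for _, g in scored]
    alleles = frozenset().union(*typed)
    fully_typed = (
        father is not None
        and mother is not None
        and all(g for _, g in offspring)
    )
    if len(alleles) < 2 and fully_typed:
        return CATEGORY_UNINFORMATIVE  # monomorphic: nothing segregates

    daughters = [g for sex, g in scored if sex == "female"]
    sons = [g for sex, g in scored if sex == "male"]
    budget = params.max_violation_rate * n

    # X-linked: paternal allele in all daughters, none in sons; sons
    # hemizygous for a maternal allele
    if father is not None and len(father) == 1 and daughters and sons:
        pat = next(iter(father))
        violations = sum(pat not in d for d in daughters)
        violations += sum(
            (pat in s)
            or len(s) > 1
            or (mother is not None and not s <= mother)
            for s in sons
        )
        if violations <= budget:
            return CATEGORY_X

    # Y-linked: paternal allele (absent from the mother) in all sons and
    # no daughters; untyped mother/daughters are consistent (no Y copy)
    if father is not None and len(father) == 1 and sons:
        pat = next(iter(father))
        if mother is None or pat not in mother:
            violations = sum((pat not in s) or len(s) > 1 for s in sons)
            violations += sum(pat in d for d in daughters)
            if violations <= budget:
                return CATEGORY_Y

    # autosomal: one allele from each parent, either sex
    if father is not None and mother is not None:
        violations = 0
        for _, g in scored:
            explained = any(
                g == frozenset({pf, pm}) for pf in father for pm in mother
            )
            violations += not explained
        if violations <= budget:
            return CATEGORY_AUTOSOMAL

    return CATEGORY_UNINFORMATIVE


def _family_from_frame(sub: pd.DataFrame, contig: str):
    father = mother = None
    offspring: list[tuple[str, Genotype | None]] = []
    n_father = n_mother = 0
    for row in sub.itertuples(index=False):
        try:
            genotype = parse_genotype(row.allele1, row.allele2)
        except ValueError as err:
            raise ValueError(f"contig {contig!r}, individual {row.individual!r}: {err}")
        role = str(row.role).lower()
        if role == "father":
            father, n_father = genotype, n_father + 1
        elif role == "mother":
            mother, n_mother = genotype, n_mother + 1
        else:
            sex = str(row.sex).lower()
            if sex not in ("male", "female"):
                raise ValueError(
                    f"contig {contig!r}: offspring {row.individual!r} has "
                    f"unrecognized sex {row.sex!r}"
                )
            offspring.append((sex, genotype))
    if n_father > 1 or n_mother > 1:
        raise ValueError(f"contig {contig!r}: more than one father or mother")
    return father, mother, offspring


def classify_all(
    table: pd.DataFrame,
    params: SegParams = SegParams(),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every contig in a long genotype table.

    ``table`` columns: contig, individual, role (mother/father/offspring),
    sex, allele1, allele2.  Returns a per-contig classification frame and a
    summary dict with counts and proportions (assigned vs uninformative,
    sex-linked vs autosomal among assigned).
    """
    required = {"contig", "individual", "role", "sex", "allele1", "allele2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"genotype table missing columns {sorted(missing)}")
    if table.empty:
        raise ValueError("genotype table is empty")

    rows = []
    for contig, sub in table.groupby("contig", sort=True):
        father, mother, offspring = _family_from_frame(sub, str(contig))
        rows.append(
            {
                "contig": contig,
                "category": classify_contig(father, mother, offspring, params),
            }
        )
    result = pd.DataFrame(rows)

    counts = result["category"].value_counts()
    n = len(result)
    n_x = int(counts.get(CATEGORY_X, 0))
    n_y = int(counts.get(CATEGORY_Y, 0))
    n_auto = int(counts.get(CATEGORY_AUTOSOMAL, 0))
    n_assigned = n_x + n_y + n_auto
    summary = {
        "n_contigs": n,
        "n_assigned": n_assigned,
        "n_x_linked": n_x,
        "n_y_linked": n_y,
        "n_autosomal": n_auto,
        "n_uninformative": n - n_assigned,
        "prop_assigned": n_assigned / n,
        "prop_sex_linked_among_assigned": (
            (n_x + n_y) / n_assigned if n_assigned else float("nan")
        ),
    }
    return result, summary
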