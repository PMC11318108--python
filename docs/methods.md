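# Methods

## Quantification model

The pipeline infers X-chromosome copy number from relative qPCR dosage.
For sample *s*, X-linked marker *x*, autosomal normalizer *a* and the
plate's two-X female reference *r*:

    dCt_s  = Ct(x, s) − Ct(a, s)
    ddCt_s = dCt_s − dCt_r
    fold_s = A_x^(−ddCt_s)

`A_x` is the marker's amplification factor (template multiplication per
cycle), a panel constant measured once per primer from a standard curve
(`A = 10^(−1/slope)`, slope of Ct on log10 concentration by ordinary least
squares; efficiency in percent is `(A − 1)·100`).  With one X copy and
ideal amplification the fold is exactly 0.5; with two it is exactly 1.0,
independent of `A` as long as the generator/assay and the analysis agree
on it.

**Sign convention.**  dCt is defined as *X minus autosomal*.  The reverse
order, sometimes written in protocol prose, would place single-X samples
at fold 2.0 rather than the dosage expectation 0.5; the convention here is
the one consistent with expected male/female values of 0.5/1.0.

**Efficiency correction modes.**  `single_factor` (default) raises the
X-primer's factor to −ddCt, treating the autosomal Ct difference purely as
a within-plate normalizer.  `efficiency_ratio` applies each primer's own
factor to its own Ct difference (a Pfaffl-style ratio),
`A_x^(−ΔCt_x) / A_a^(−ΔCt_a)`.  The two coincide when the factors are
equal or when the sample's autosomal Ct matches the reference's.  Both are
exposed because assay descriptions are frequently ambiguous about which
primer's factor is meant; results in this package's tests use the default.

**Per-plate computation.**  Every plate carries its own female reference;
folds are computed within a plate and concatenated.  A sample run on
several plates gets one fold per plate and marker; consensus calling
combines repeated (sample, marker) folds by geometric mean, the natural
mean for ratios.

## QC filter chain

Four criteria, applied in a fixed order per plate (defaults in
parentheses):

1. wells with missing Ct or Ct strictly above the cutoff (26.5 cycles)
   are discarded individually — late amplification is treated as
   non-quantitative;
2. per sample×target, if the sample standard deviation (n−1 denominator)
   of the *surviving* replicates exceeds the maximum (0.5 cycles, compared
   with ≤), the whole sample×target is discarded;
3. fewer than the minimum surviving replicates (2 of 3) discards the
   sample×target; with exactly one survivor the SD is undefined and the
   target fails here regardless;
4. a sample whose autosomal normalizer was discarded loses all its
   targets — no dCt is computable.

The order is semantic, not cosmetic: the SD in (2) is computed only over
replicates that survived (1), and a property test asserts the equivalence
of filtering and pre-deleting the criterion-1 wells.  Every discarded
well/target/sample is written to an audit table with the criterion
responsible; a conservation property guarantees no well vanishes
unaccounted.

## Sex calling

Per marker: fold < 0.7 → male, fold > 0.8 → female, the closed band
[0.7, 0.8] → unspecified (thresholds strict, so the endpoints are
unspecified).  Consensus steps, in order: all-unspecified → removed;
conflicting determinate calls → removed (strict mode; a non-strict mode
resolves by majority with ties removed, provided for reproduction
experiments only); cross-marker fold SD > 0.3 → removed (the markers must
agree on the dosage value, not merely the side of a threshold; undefined
with a single available marker, which then passes).  Single-X consensus is
labeled `male_singleX`, never XY or X0 — without Y-specific markers the
karyotypes are indistinguishable.

## Cohort statistics

* `performance` scores determinate calls against phenotypic sex.
  Sensitivity and specificity are computed over called samples; removed
  samples are excluded from the 2×2 and reported separately, with
  per-class called fractions exposing the cost of strict filtering (a
  removed male lowers `called_fraction_positive`, not sensitivity).  Male
  is the default positive class; `performance_both` reports both to avoid
  a hidden convention.
* `filter_bias_test` is a Pearson χ² on the 2×2 failed/passed table, df 1,
  Yates continuity correction on by default (the default of R's
  `chisq.test`, the environment such analyses are usually scripted in);
  a zero margin raises rather than returning a meaningless statistic.
* `single_x_proportion` restricts to adults by default: under gynogenesis
  an XX mother can only produce XX offspring, so including broods would
  underrepresent single-X genotypes.  The Clopper–Pearson interval is
  reported as additional information (exact, conservative).
* `family_ratios` infers the mother's genotype per brood: any single-X
  offspring implies a single-X mother; an all-XX brood implies an XX
  mother, flagged `small_sample` below 5 called offspring (with brood
  single-X rates near 0.25, a brood of 4 misses the single-X class with
  probability ≈ 0.32); fewer than 2 called offspring is indeterminate.

## Synthetic data generator

Ct values are drawn from a log-linear amplification model:

    Ct = B_m − log_{A_m}(c/2 · input_scale) + δ_s + ε

with `c` the true copy number (2, or 1 at X markers of single-X samples),
`B_m` the marker's baseline Ct of a two-copy sample at standard 5 ng
input, `δ_s ~ N(0, σ_smp)` a sample-level offset shared by all wells of a
sample (cancelled exactly by the within-sample dCt), and
`ε ~ N(0, σ_rep)` independent per well.  With probability `p_out` a well
additionally gains a fixed upward shift (late amplification / partial
inhibition; instrument outliers in this assay are one-sided).  Ct values
are continuous — no instrument quantization is modeled, as the analysis
consumes continuous Ct.

Defaults, chosen once as the simulated study conditions: triplicates;
`σ_rep = 0.15` cycles (makes per-marker fold scatter of roughly ±0.1,
the magnitude typical of validated assays; replicate noise is rarely
published, so this is a realism choice, not a fit); `σ_smp = 0.2`;
`p_out = 0.05`; outlier shift 4.0 cycles; baselines 23.5–24.4 cycles so
that two-copy samples sit well below the 26.5 cutoff while outlier wells
land clearly above it; amplification factors 1.91–1.98 (91–98%
efficiency).  Expected folds are `c/2` regardless of `A`, so realistic
factors do not bias the dosage clusters.

The generator emulates triplicate plate structure, per-plate references,
dilution series, gynogenetic broods (XX mothers → all-XX; single-X
mothers → single-X offspring at a set rate) and one-family crosses with
X-linked, Y-linked and autosomal loci and symmetric genotype corruption.
It does **not** emulate: inter-plate batch effects beyond the per-plate
reference mechanism, efficiency drift between runs, plate-position
artifacts, melting-curve failures, or contamination.  Passing tests on
synthetic cohorts therefore demonstrate the correctness and robustness of
the *analysis logic* under the stated noise model, not the wet-lab
performance of any particular primer set on real samples.

## Segregation classifier

`seglink` assigns loci of a single mother/father/sexed-offspring family to
x_linked / y_linked / autosomal / uninformative by deterministic Mendelian
rules: X-linked requires a single-allele father whose allele reaches every
daughter and no son, with sons hemizygous for maternal alleles; Y-linked
requires a paternal allele absent from the mother present in every son and
no daughter (mother and daughters may lack the locus entirely, as in
expression data); autosomal requires every offspring genotype to be
explainable as one allele from each parent.  Checks run in the order X, Y,
autosomal; violations up to `max_violation_rate` of scored offspring are
tolerated (default 0).  Loci with missing parents, fewer than
`min_informative_offspring` (default 2) scorable offspring, or no
segregating variation among fully typed members stay uninformative.
Genotypes are unphased allele sets; hemizygous and homozygous-looking
fathers are deliberately not distinguished.  This is a transparent
rule-based classifier for demonstrating and testing the discovery logic on
crosses; it is not a reimplementation of probabilistic segregation
inference (e.g. posterior-based tools), which additionally model
genotyping error and incomplete transmission.

## Numerical conventions and degenerate inputs

* All SDs are sample standard deviations (ddof = 1).
* Threshold comparisons: QC cutoff strict `>`; QC SD `≤`; call thresholds
  strict `<` / `>`; marker-SD filter strict `>`.
* Missing Ct (`Undetermined`) fails criterion 1; malformed or non-positive
  Ct cells are parsed as missing and reported with their file line number.
* A plate whose reference sample fails QC raises a plate-level error —
  nothing on that plate is quantifiable, and silently dropping the plate
  would bias cohorts.
* Standard curves with non-negative slope are returned flagged invalid
  rather than raising, so batch curve-fitting can report them.
* `family_ratios` leaves `ratio_x_to_xx` undefined (NaN) when no XX
  offspring were called.

## Problem sizes in tests

The bundled test suite and acceptance checks use cohorts of 30–61 samples
per plate, 20 replicate seeds for the stochastic specificity/sensitivity
property, 200–500 loci for classifier oracles and ~1000 randomized cases
across the QC/fold property tests — sizes at which every documented effect
is comfortably resolvable while the whole suite stays fast.

## Known limitations

* One autosomal normalizer is the intended design; with several, their
  mean Ct (and mean factor in ratio mode) is used.
* The 0.7/0.8/0.3 decision thresholds are assay-specific constants, not
  estimated from data; recalibrate them for other panels.
* Specificity/sensitivity are meaningful only against trusted phenotypes;
  in feminized cohorts the "phenotypic sex" is itself the quantity under
  study, and `performance` should be read as concordance, not accuracy.
* The classifier assumes a single family; multi-family designs require
  running it per family and reconciling.
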