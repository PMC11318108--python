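"""Genotype ratios in gynogenetic broods and cohort proportions.

Simulates six all-female broods — four from XX mothers, two from single-X
mothers producing single-X offspring at rate 0.25 — runs the full sexing
pipeline on one plate, infers each mother's genotype from her offspring,
and tests whether QC removed samples unevenly between two groups.
"""

from xdosage import (
    SampleTruth,
    SynthConfig,
    family_frame,
    family_ratios,
    filter_bias_test,
    run_sexing,
    simulate_family,
    simulate_plate,
)

samples = []
for i, mother in enumerate(["XX", "XX", "XX", "XX", "singleX", "singleX"], 1):
    samples += simulate_family(
        mother, 10, single_x_ratio=0.25, seed=100 + i, family_id=f"F{i}"
    )
reference = SampleTruth("REF", "XX", haplotype="HT2", phenotypic_sex="female")

config = SynthConfig(seed=7)
plate, truth = simulate_plate(config, samples + [reference], "REF")
result = run_sexing(plate, config.panel())

reports = family_ratios(result.assignment_table, truth)
print(family_frame(reports).to_string(index=False))
print(
    "\nA brood containing any single-X offspring implies a single-X mother; "
    "all-XX broods imply an XX mother (flagged small_sample when too few "
    "offspring were callable to rule out a missed single-X)."
)

chi2 = filter_bias_test(group_a=(1, 14), group_b=(9, 39))
print(
    f"\nfilter-bias test (failed/passed in two groups): "
    f"X2 = {chi2.statistic:.3f}, df = {chi2.df}, p = {chi2.p_value:.3f}"
)
print("A large p-value means QC did not disadvantage either group.")
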