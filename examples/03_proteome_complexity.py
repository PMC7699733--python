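"""Per-sample proteome complexity and its association with outcome.

A protein counts as "unique" when detected in exactly one sample of the
cohort; poor-outcome samples (stage IV or deceased) are tested against the
rest with the Wilcoxon rank-sum test, exactly when group sizes and ties
allow.
"""

from evbal import (
    SimulationConfig,
    complexity_association,
    generate_cohort,
    unique_protein_counts,
    wilcoxon_rank_sum,
)

quant, meta, truth = generate_cohort(SimulationConfig(seed=1))
counts = unique_protein_counts(quant)  # only the zero-pattern matters
print("unique proteins per sample:")
print(counts.to_string())

res = complexity_association(counts, meta, contrast="stage4_or_dead")
print(f"\nWilcoxon rank-sum W = {res.statistic:.1f}, "
      f"two-sided p = {res.p_value:.2e} ({res.mode_used}); {res.direction}")

# the exact small-sample machinery, on a textbook example
W, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
print(f"exact test on fully separated 3v3 ranks: W = {W:.0f}, p = {p}")
# A small p says the poor-outcome samples carry systematically more
# proteins seen nowhere else - the tumor-heterogeneity signature.
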