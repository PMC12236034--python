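"""Generate a synthetic transplant cohort and inspect its structure.

The generator draws correlated mixed-type features from a low-rank latent
factor model, assigns each case a haemoglobin value (g/L), and thresholds it
at 115/150 into normal (0) / low (1) / high (2) classes with a severely
imbalanced mix.
"""

import numpy as np

import hbpredict as hp

cfg = hp.GeneratorConfig(seed=0)  # 854 cases, 95 features in three tiers
table, labels = hp.generate_cohort(cfg)

counts = hp.class_distribution(labels)
print(f"cohort: {table.n_samples} cases x {table.n_features} features")
print("class counts:", counts["counts"])
# e.g. {0: 389, 1: 449, 2: 16} — close to the configured 390:447:17 mix

masked = hp.inject_tiered_missingness(table, (0.0, 0.05, 0.25), seed=0)
for tier in hp.MissingnessTier:
    cols = table.columns_of_tier(tier)
    frac = masked.mask[:, cols].mean()
    print(f"tier {tier.value:>10}: {cols.size:2d} features, "
          f"{100 * frac:5.1f}% missing")
# The always-observed tier stays complete; the two fillable tiers carry the
# low / relatively-high missing rates the imputation stage expects.

blocked, deleted = hp.inject_missingness(table, 0.10, seed=0)
print(f"worst-case block deletion: {deleted.size} cases lost every "
      "fillable entry")
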