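"""Train the five learner families with and without ECOC and compare them.

ECOC encodes each class as a binary codeword, trains one binary model per
bit, and decodes predictions by minimum Hamming distance.  It is mandatory
for the binary-only max-margin families and acts as an ensemble wrapper for
the tree families.
"""

import warnings

import numpy as np

import hbpredict as hp

warnings.filterwarnings("ignore")

cfg = hp.GeneratorConfig(n_samples=600, n_features_per_tier=(10, 14, 10),
                         class_mix=(0.45, 0.45, 0.10), class_sep=2.0, seed=3)
table, labels = hp.generate_cohort(cfg)
tr, te = hp.stratified_split(table, labels, hp.SplitSpec(seed=3))
x, y = table.values, labels.labels

code = hp.build_code_matrix(3)  # exhaustive: 3 bits for 3 classes
print("code matrix (classes x bits):")
print(code.matrix)

specs = [(hp.LearnerSpec(f, seed=3), True)
         for f in ("rf", "xgb", "lgbm", "linsvc", "polysvm")]
report = hp.compare_models(specs, x[tr], y[tr], x[te], y[te])
print(report["markdown"])
# Columns A/B are test-set accuracy without/with ECOC; the max-margin
# families have no A column because they cannot do 3-class natively.
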