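"""Rank features by boosted-tree importance and prune them with RFE.

Recursive feature elimination repeatedly drops the least important features,
tracking cross-validated accuracy, and keeps the smallest subset whose
accuracy stays within a relative tolerance of the full model.
"""

import warnings

import numpy as np

import hbpredict as hp

warnings.filterwarnings("ignore")

rng = np.random.default_rng(0)
x = rng.standard_normal((400, 30))
w = np.array([2.0, -2.0, 1.5, -1.5, 1.0])  # five features carry the signal
score = x[:, :5] @ w + 0.5 * rng.standard_normal(400)
y = np.digitize(score, np.quantile(score, [0.4, 0.8]))

rep = hp.rank_importance(x, y, seed=0)
print("top features:", rep.ranking[:6])

sel = hp.rfe_select(x, y, tolerance=0.01, step=5, seed=0)
print(f"retained {sel.n_retained} of 30 features "
      f"(full accuracy {sel.full_accuracy:.3f}, "
      f"relative loss {100 * sel.relative_loss:.2f}%)")
print("retained:", sorted(sel.retained))
# The five planted features survive the pruning; the 25 noise columns go.

lasso = hp.lasso_crosscheck(x, (y > 0).astype(int), seed=0)
print("LASSO cross-check selects:", sorted(lasso["selected"]))
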