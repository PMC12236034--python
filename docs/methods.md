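# Methods

## The problem setting

The pipeline targets small clinical cohorts (hundreds of cases, ~100 mixed
continuous/categorical features) with structured missingness and a severely
imbalanced multiclass outcome.  The concrete instantiation is post-kidney-
transplant haemoglobin: the 30-day Hb concentration (g/L) thresholded into
low (< 115), normal (115–150, boundaries inclusive), and high (> 150), with
the high class rare (~2% of cases).  The real cohorts for this problem are
private, so the package ships a generator that reproduces the statistical
structure the methods rely on, and every claim the tests make is a claim
about that structure.

## Synthetic cohort generator

Each case draws a class c from the configured mix, a latent factor vector
z = μ_c + ε with ε ~ N(0, I_r), and features x = Wz + noise, with loadings
W scaled by 1/√r.  Haemoglobin is drawn inside the class's threshold band,
so labels are exactly the thresholded image of Hb.  Categorical features are
latent scores cut at tertiles and integer-coded.

Defaults (fixed once, as the package's reference conditions): n = 854 cases;
95 features split 25/40/30 over the three missingness tiers; latent rank 6;
observation noise SD 0.3; class mix 390:447:17/854; class separation 3.0 in
latent space; 15% categorical features per tier.  Two missingness mechanisms
are provided: entrywise MCAR with per-tier rates (0, 0.05, 0.25 by default —
the always-observed tier never masks; the other two rates are conventions
standing in for "low" and "relatively high" missing probability), and
worst-case block deletion, where a fraction of cases (rounded to the nearest
count, at least one) lose *every* fillable entry at once, keeping only
demographics and pre-operative values.

What the generator does not emulate: named clinical variables, MNAR
missingness, measurement ceilings/floors, longitudinal structure, site
effects.  Passing tests therefore demonstrate correct algorithmic behaviour
on correlated low-rank tabular data, not clinical validity on any real
cohort.

## Imputation

Missingness is handled tier by tier.  The rarely-missing tier is filled by
unweighted k-NN (k = 5): row similarity is Euclidean distance over the
z-scored always-observed columns, the fill is the mean (majority vote for
categoricals, ties to the lowest code) of the k nearest rows where the
target is observed, distance ties broken by row index.  With k equal to the
whole reference pool this provably degenerates to mean filling.

The often-missing tier is filled by a chained feed-forward network, visiting
features in ascending missingness (best-supported first).  For each feature
the net trains on the cases where it is observed, with predictors = the
always-observed tier ∪ the (now complete) rarely-missing tier ∪ every
previously chained feature — the predictor pool grows by exactly one per
step.

Two choices here are the package's own:

1. **Consistent training view.**  Predictor columns that were imputed
   upstream are presented to the learner as leave-one-out KNN estimates for
   *all* rows, and previously chained features enter as the chain's fitted
   values.  Without this, the net trains on true lab values but predicts
   from KNN estimates; under block deletion that covariate shift is severe
   enough to push the fused method behind plain KNN.  This is the
   stacked-generalization convention (train level-1 models on level-0
   *predictions*).  Its cost: under light entrywise missingness the view
   discards genuinely observed predictor values for the rows being filled.
2. **Network defaults.**  One hidden layer of 16 units, L-BFGS, L2 penalty
   α = 10, max 200 iterations.  At these sample sizes a lightly regularized
   wider net overfits; heavy shrinkage keeps the fit close to the smooth
   low-dimensional relations that dominate correlated clinical tables.  Any
   regressor satisfying the chaining contract can be substituted via
   `MlpSpec`.

Fill quality is scored as the mean, over deleted cases, of the Euclidean
distance between the true and filled case vectors restricted to fillable
features.  Distances are computed on z-scored features (truth-table
statistics), making the metric scale-invariant; absolute values are
therefore not comparable with distances computed on raw scales.  On the
default cohort under 10% block deletion the ordering is
fused < KNN-only < mean filling, consistently across seeds.

## Balancing (ADASYN)

For each minority class c (strategy `not_majority`; `minority` restricts to
the smallest class only), G = (n_majority − n_c)·β synthetics are generated,
β = 1 by default.  Per-member quotas are proportional to the fraction of
non-minority points among the member's k = 5 nearest neighbours in the
z-scored feature space (uniform if that density signal is identically zero),
rounded by largest remainder so the total is exactly G.  Each synthetic is
x + λ(x′ − x) with λ ~ U(0,1) and x′ drawn among the k nearest same-class
points; categorical entries are copied from the nearer parent.  Classes with
fewer than k + 1 members are skipped with a warning.  Real rows are
preserved bit-exact and precede all synthetics.

In pipeline mode balancing is applied to the **training partition only**,
after the split — balancing before splitting leaks synthetic copies of
test-neighbourhood information into training.  Both orders are supported;
train-only is the default.

## Feature screening

Importance is normalized total gain from an XGBoost fit (100 trees, depth 4,
learning rate 0.3 by default), stable-sorted with name tie-breaks.  RFE
drops the `step` lowest-importance features per round (re-fitting the
ranking each round), records stratified-CV accuracy at every visited size,
and retains the smallest size whose accuracy ≥ (1 − tolerance) × the
full-feature accuracy; tolerance defaults to 0.001.  The LASSO cross-check
runs an L1-logistic path (liblinear) over an inverse-regularization grid on
a binarized outcome and reports the nonzero set at the CV-AUC-maximizing
penalty; it is a qualitative overlap check, not a selector.

## Class-count selection

"Ideal" clusterings come from K-means on z-scored features (10 k-means++
restarts; additionally a warm start from the previous K's centres plus the
worst-fit point, which guarantees the recorded SSE curve is non-increasing
in K).  The elbow is automated as the maximum discrete second difference of
SSE (ties to the smaller K; a curvature-free curve returns the smallest K
with a warning); the silhouette selector is the argmax of mean silhouette.
"Actual" partitions are clinical: 2 = normal vs abnormal, 3 = the 115/150
thresholds, 4 = low additionally split at a severity threshold (80 g/L by
default); the 2- and 4-class schemes are explicit configuration, since only
the 3-class thresholds are clinically canonical.  For each candidate K the
actual partition is compared with the K-cluster ideal assignment by NMI,
homogeneity, completeness, and V-measure (harmonic mean of the latter two,
computed with the clinical partition as the reference); the chosen class
count maximizes V-measure, ties resolved toward the elbow K, then the
smaller K.

## ECOC models

Exhaustive codes are the default for C ≤ 7: one column per non-degenerate
bipartition up to complement, M = 2^(C−1) − 1 (for C = 3: three columns).
A `random_dense` sampler (best-of-200 by minimum pairwise row Hamming
distance) covers larger C.  Validity is enforced structurally: distinct
rows, no constant column, no duplicate or complementary columns, M ≥
log2(C).

Decoding is minimum Hamming distance between the hard bit predictions and
the class rows.  Ties break by the Euclidean distance between the per-bit
probability vector (predict_proba, or a logistic squash of the margin) and
the class row, then by the lowest class index.  The per-class score is
−(Hamming + soft/(√M + 1)): the soft term is strictly below 1, so the score
ranking reproduces the decode order exactly while remaining continuous
enough for ROC analysis — hard decoding alone yields no usable scores for
micro-AUC.

Base families: random forest (200 trees), XGBoost (100 trees, depth 4),
LightGBM (100 trees), linear SVC and degree-3 polynomial SVM (both behind a
standardizing pipeline).  The two max-margin families are binary-only;
requesting native multiclass prediction from them is a configuration error —
they exist in the comparison precisely to show ECOC making them multiclass.

## Evaluation

Splits are stratified per class at the configured fraction (0.8), rounding
per class and keeping both sides nonempty; singleton classes go to training
with a warning.  Cross-validation is stratified k-fold (10 by default,
reduced with a warning when the rarest class is smaller), aggregating a
mean report and the elementwise mean confusion matrix.  Metrics: accuracy;
one-vs-rest per-class precision/recall/F1 with zero-division pinned to 0
(warned); macro = unweighted means, weighted = support-weighted means;
micro-AUC = a single ROC over the flattened one-hot labels against the
flattened per-class scores.  EPP = n·years·event-rate / predictors, with the
conventional adequacy floor of 10.

## Numerical conventions

Zero-variance columns z-score with SD 1.  Categorical ties resolve to the
lowest code; neighbour-distance ties to the lowest row index; all stochastic
components consume explicit integer seeds and are bitwise reproducible.
Chained features with fewer than 10 observed rows fall back to mean filling
with a warning.

## Problem sizes used by the shipped checks

The test suite and acceptance script run the imputation benchmark at the
full reference cohort (854 × 95, 20 deletion seeds) and scale other
simulations to the size at which the property under test is decisive:
planted-feature recovery at 400 × 95 with 10 seeds, class-count recovery at
300 × 24 over 5 seeds (latent rank 2, separation 6 — parameters at which the
cohort is unambiguously trimodal in feature space), model comparison at
600 × 68.  These sizes are the package's reference experiments, chosen so
each structure being recovered is genuinely present in the data.

## Known limitations

- Absolute imputation distances depend on the z-scoring convention and are
  not comparable across scalings of the same data.
- ADASYN interpolation treats integer-coded categoricals as copy-from-parent;
  no categorical distance metric is used.
- The ECOC soft scores are a reconstruction for ROC purposes, not calibrated
  probabilities.
- The consistent-view chaining discards observed predictor values for rows
  being filled when a column was imputed anywhere upstream; under light
  entrywise missingness a hybrid view could do better.
- Why ECOC sometimes helps natively multiclass tree models is measured, not
  explained, by this package.
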