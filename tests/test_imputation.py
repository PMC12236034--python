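"""Fillers: arithmetic oracles, chaining contract, observed-value preservation."""

import numpy as np
import pytest

import hbpredict as hp
from hbpredict.cohort import MissingnessTier
from hbpredict.imputation import MlpSpec

T = MissingnessTier


def _mask_at(shape, cells):
    m = np.zeros(shape, dtype=bool)
    for r, c in cells:
        m[r, c] = True
    return m


def test_mean_fill_arithmetic(tiny_factory):
    t = tiny_factory([[1.0, 1.0], [3.0, 2.0], [5.0, 3.0]],
                     [T.NO_MISSING, T.NOT_EASY],
                     mask=_mask_at((3, 2), [(2, 1)]))
    res = hp.mean_fill(t)
    assert res.table.values[2, 1] == pytest.approx((1 + 2) / 2)
    assert res.provenance[2, 1] == "mean"


def test_mean_fill_mode_for_categorical(tiny_factory):
    t = tiny_factory([[0, 0.0], [0, 0.0], [0, 1.0], [0, 0.0]],
                     [T.NO_MISSING, T.NOT_EASY],
                     kinds=["continuous", "categorical"],
                     mask=_mask_at((4, 2), [(3, 1)]))
    assert hp.mean_fill(t).table.values[3, 1] == 0.0


def test_mean_fill_noop_without_missing(tiny_factory):
    t = tiny_factory([[1.0, 2.0]], [T.NO_MISSING, T.NOT_EASY])
    res = hp.mean_fill(t)
    assert np.array_equal(res.table.values, t.values)
    assert (res.provenance == "observed").all()


def test_mean_fill_fully_missing_column_named(tiny_factory):
    t = tiny_factory([[1.0, 0.0], [2.0, 0.0]], [T.NO_MISSING, T.NOT_EASY],
                     mask=_mask_at((2, 2), [(0, 1), (1, 1)]))
    with pytest.raises(hp.UnfillableColumnError, match="f1"):
        hp.mean_fill(t)


def test_knn_nearest_neighbour_copy(tiny_factory):
    # row 3 duplicates row 0 on the NO_MISSING feature; k=1 copies row 0
    t = tiny_factory([[0.0, 10.0], [5.0, 20.0], [9.0, 30.0], [0.0, 0.0]],
                     [T.NO_MISSING, T.NOT_EASY],
                     mask=_mask_at((4, 2), [(3, 1)]))
    res = hp.knn_fill(t, features=["f1"], k=1)
    assert res.table.values[3, 1] == 10.0
    assert res.provenance[3, 1] == "knn"


def test_knn_equals_mean_when_k_is_pool(tiny_factory):
    vals = [[0.0, 1.0], [1.0, 4.0], [2.0, 7.0], [3.0, 0.0]]
    t = tiny_factory(vals, [T.NO_MISSING, T.NOT_EASY],
                     mask=_mask_at((4, 2), [(3, 1)]))
    res = hp.knn_fill(t, features=["f1"], k=3)
    assert res.table.values[3, 1] == pytest.approx(np.mean([1, 4, 7]))


def test_knn_brute_force_oracle(tiny_factory):
    """5-row fixture, k=2: the fill equals the mean of the two nearest rows
    found by an independent brute-force search."""
    base = np.array([[0.0, 0.0], [1.0, 0.5], [3.0, 3.0], [0.2, 0.1], [2.5, 2.0]])
    target = np.array([10.0, 11.0, 30.0, 12.0, 0.0])
    vals = np.column_stack([base, target])
    t = tiny_factory(vals, [T.NO_MISSING, T.NO_MISSING, T.NOT_EASY],
                     mask=_mask_at((5, 3), [(4, 2)]))
    res = hp.knn_fill(t, features=["f2"], k=2)

    # oracle: z-score the distance features, scan candidate rows
    ref = [0, 1, 2, 3]
    mu, sd = base.mean(axis=0), base.std(axis=0)
    z = (base - mu) / sd
    d = [float(np.linalg.norm(z[4] - z[r])) for r in ref]
    nearest = [ref[i] for i in np.argsort(d, kind="stable")[:2]]
    expected = target[nearest].mean()
    assert res.table.values[4, 2] == pytest.approx(expected)


def test_knn_clamps_large_k(tiny_factory):
    t = tiny_factory([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]],
                     [T.NO_MISSING, T.NOT_EASY],
                     mask=_mask_at((3, 2), [(2, 1)]))
    with pytest.warns(UserWarning, match="clamping"):
        res = hp.knn_fill(t, features=["f1"], k=10)
    assert res.table.values[2, 1] == pytest.approx(1.5)


def test_mlp_noop_without_missing(small_cohort):
    table, _ = small_cohort
    res = hp.mlp_iterative_fill(table)
    assert np.array_equal(res.table.values, table.values)


def test_mlp_learns_noiseless_linear_relation():
    """Rank-1 noiseless data: each chained feature is an exact linear map of
    the predictors, so the reconstruction error is tiny."""
    cfg = hp.GeneratorConfig(n_samples=300, n_features_per_tier=(6, 6, 6),
                             latent_rank=1, noise_sd=0.0,
                             categorical_fraction=0.0, seed=2)
    table, _ = hp.generate_cohort(cfg)
    masked = hp.inject_tiered_missingness(table, (0.0, 0.0, 0.3), seed=3)
    rows = np.flatnonzero(masked.mask.any(axis=1))
    spec = MlpSpec(alpha=1e-4, max_iter=500)
    res = hp.mlp_iterative_fill(masked, mlp_spec=spec)
    easy = table.columns_of_tier(T.EASY)
    truth = table.values[np.ix_(rows, easy)]
    filled = res.table.values[np.ix_(rows, easy)]
    scale = table.values[:, easy].std(axis=0)
    assert np.abs((filled - truth) / scale).max() < 0.1


def test_mlp_predictor_pool_grows_by_one(small_cohort):
    """Each newly filled feature joins the predictor pool of the next."""
    table, _ = small_cohort
    masked, _ = hp.inject_missingness(table, 0.1, seed=5)
    stage1 = hp.knn_fill(masked, features=[
        table.meta[j].name for j in table.columns_of_tier(T.NOT_EASY)])
    res = hp.mlp_iterative_fill(stage1.table)
    pools = [n for _, n in res.fill_log]
    assert len(pools) == table.columns_of_tier(T.EASY).size
    assert all(b - a == 1 for a, b in zip(pools, pools[1:]))


def test_fused_reduces_to_knn_when_only_not_easy_missing(small_cohort):
    table, _ = small_cohort
    ne = table.columns_of_tier(T.NOT_EASY)
    masked = table.copy()
    rng = np.random.default_rng(0)
    masked.mask[np.ix_(rng.choice(200, 30, replace=False), ne)] = True
    fused = hp.fused_fill(masked)
    knn = hp.knn_fill(masked, features=[table.meta[j].name for j in ne])
    assert np.array_equal(fused.table.values, knn.table.values)


def test_fused_completes_and_preserves_observed(small_cohort):
    table, _ = small_cohort
    masked, rows = hp.inject_missingness(table, 0.1, seed=6)
    res = hp.fused_fill(masked)
    assert not res.table.mask[:, table.fillable_columns].any()
    obs = ~masked.mask
    assert np.array_equal(res.table.values[obs], table.values[obs])
    knn_cols = set(table.columns_of_tier(T.NOT_EASY))
    tagged = {(r, c) for r, c in zip(*np.where(res.provenance == "knn"))}
    assert tagged and all(c in knn_cols for _, c in tagged)


def test_evaluate_fill_arithmetic(tiny_factory):
    truth = tiny_factory([[0.0, 0.0], [0.0, 3.0]], [T.NO_MISSING, T.NOT_EASY])
    filled = tiny_factory([[0.0, 4.0], [0.0, 0.0]], [T.NO_MISSING, T.NOT_EASY])
    # z-scoring divides by the truth column sd (1.5 here)
    sd = np.std([0.0, 3.0])
    d1, d2 = 4.0 / sd, 3.0 / sd
    res = hp.evaluate_fill(truth, filled, np.array([0, 1]))
    assert res.mean_distance == pytest.approx((d1 + d2) / 2)
    # order of deleted cases is irrelevant
    res2 = hp.evaluate_fill(truth, filled, np.array([1, 0]))
    assert res2.mean_distance == pytest.approx(res.mean_distance)


def test_evaluate_fill_zero_for_perfect(small_cohort):
    table, _ = small_cohort
    assert hp.evaluate_fill(table, table, np.array([0, 5])).mean_distance == 0.0
    with pytest.raises(ValueError):
        hp.evaluate_fill(table, table, np.array([], dtype=int))


def test_compare_methods_order_and_shape(small_cohort):
    table, _ = small_cohort
    out = hp.compare_fill_methods(table, seeds=[0])
    assert [a.method for a in out] == ["mean", "knn", "fused"]
    assert all(a.mean_distance >= 0 for a in out)
    with pytest.raises(ValueError):
        hp.compare_fill_methods(table, seeds=[])
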