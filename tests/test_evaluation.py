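"""Splits, metric identities, CV aggregation, model comparison, EPP."""

import numpy as np
import pytest

import hbpredict as hp


def test_stratified_split_exact_arithmetic():
    y = np.repeat([0, 1, 2], [50, 30, 20])
    tr, te = hp.stratified_split(np.zeros((100, 2)), y, hp.SplitSpec(seed=0))
    assert [int((y[tr] == c).sum()) for c in range(3)] == [40, 24, 16]
    assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(100))
    assert np.intersect1d(tr, te).size == 0


def test_stratified_split_two_per_class():
    y = np.array([0, 0, 1, 1])
    tr, te = hp.stratified_split(np.zeros((4, 1)), y,
                                 hp.SplitSpec(train_fraction=0.5, seed=1))
    assert [int((y[tr] == c).sum()) for c in (0, 1)] == [1, 1]


def test_stratified_split_singleton_class_warns():
    y = np.array([0, 0, 0, 0, 1])
    with pytest.warns(UserWarning, match="single member"):
        tr, te = hp.stratified_split(np.zeros((5, 1)), y,
                                     hp.SplitSpec(seed=0))
    assert 4 in tr


def test_constant_classifier_metrics():
    """Majority-vote predictions on a 60/30/10 split: accuracy 0.6 and
    macro-F1 the mean of (0.75, 0, 0)."""
    y = np.repeat([0, 1, 2], [60, 30, 10])
    pred = np.zeros(100, dtype=int)
    with pytest.warns(UserWarning, match="never predicted"):
        rep = hp.compute_metrics(y, pred, classes=np.arange(3))
    assert rep.accuracy == pytest.approx(0.6)
    assert rep.macro_f1 == pytest.approx(np.mean([0.75, 0.0, 0.0]))


def test_two_class_contingency_hand_oracle():
    """Confusion {{40,10},{20,30}}: hand-computed per-class P/R/F1."""
    y = np.repeat([0, 0, 1, 1], [40, 10, 20, 30])
    pred = np.concatenate([np.zeros(40), np.ones(10), np.zeros(20), np.ones(30)])
    rep = hp.compute_metrics(y, pred.astype(int))
    c0, c1 = rep.per_class
    assert c0["precision"] == pytest.approx(40 / 60)
    assert c0["recall"] == pytest.approx(40 / 50)
    assert c1["precision"] == pytest.approx(30 / 40)
    assert c1["recall"] == pytest.approx(30 / 50)
    f1_0 = 2 * (40 / 60) * (40 / 50) / ((40 / 60) + (40 / 50))
    assert c0["f1"] == pytest.approx(f1_0)
    assert np.array_equal(rep.confusion, np.array([[40, 10], [20, 30]]))


def test_perfect_predictions():
    y = np.array([0, 1, 2, 0, 1, 2])
    scores = np.eye(3)[y]
    rep = hp.compute_metrics(y, y, scores)
    assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0 and rep.micro_auc == 1.0
    assert np.array_equal(rep.confusion, np.diag([2, 2, 2]))


def test_macro_and_weighted_identities():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 3, 200)
    pred = rng.integers(0, 3, 200)
    rep = hp.compute_metrics(y, pred)
    f1s = np.array([pc["f1"] for pc in rep.per_class])
    supports = np.array([pc["support"] for pc in rep.per_class])
    assert rep.macro_f1 == pytest.approx(f1s.mean(), abs=1e-9)
    assert rep.weighted_f1 == pytest.approx(
        (f1s * supports).sum() / supports.sum(), abs=1e-9)
    assert supports.sum() == rep.n
    # confusion rows sum to true supports
    assert np.array_equal(rep.confusion.sum(axis=1), supports)


def test_micro_auc_random_scores_near_half():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 3, 600)
    scores = rng.random((600, 3))
    rep = hp.compute_metrics(y, scores.argmax(axis=1), scores)
    assert abs(rep.micro_auc - 0.5) < 0.05


def test_cross_validate_partitions_and_determinism(separated_cohort):
    table, y = separated_cohort
    spec = hp.LearnerSpec("rf", params={"n_estimators": 30}, seed=0)
    cv = hp.cross_validate(spec, False, table, y, folds=5, seed=0)
    assert len(cv.fold_reports) == 5
    assert sum(r.n for r in cv.fold_reports) == table.n_samples
    # mean confusion = elementwise mean of fold matrices
    assert np.allclose(cv.mean_confusion,
                       np.mean([r.confusion for r in cv.fold_reports], axis=0))
    cv2 = hp.cross_validate(spec, False, table, y, folds=5, seed=0)
    assert np.allclose(cv.mean_report.accuracy, cv2.mean_report.accuracy)


def test_cross_validate_reduces_folds_for_rare_class(small_cohort):
    table, y = small_cohort
    spec = hp.LearnerSpec("rf", params={"n_estimators": 20}, seed=0)
    with pytest.warns(UserWarning, match="reducing folds"):
        cv = hp.cross_validate(spec, False, table, y, folds=10, seed=0)
    assert len(cv.fold_reports) < 10


def test_cross_validate_ecoc_path(separated_cohort):
    table, y = separated_cohort
    spec = hp.LearnerSpec("rf", params={"n_estimators": 30}, seed=0)
    cv = hp.cross_validate(spec, True, table, y, folds=3, seed=0)
    assert len(cv.fold_reports) == 3
    assert cv.mean_report.micro_auc is not None
    assert cv.mean_report.accuracy > 0.8  # separable blobs


def test_compare_models_layout_and_delta(separated_cohort):
    table, y = separated_cohort
    tr, te = hp.stratified_split(table, y, hp.SplitSpec(seed=2))
    x = table.values
    report = hp.compare_models(
        [(hp.LearnerSpec("rf", params={"n_estimators": 30}, seed=0), True),
         (hp.LearnerSpec("linsvc", seed=0), True)],
        x[tr], y.labels[tr], x[te], y.labels[te])
    rf, svc = report["models"]
    assert "native" in rf and "ecoc" in rf
    assert "native" not in svc and "ecoc" in svc  # binary-only family
    assert rf["delta"]["accuracy"] == pytest.approx(
        rf["ecoc"]["accuracy"] - rf["native"]["accuracy"], abs=1e-9)
    assert "| rf |" in report["markdown"]


def test_tree_models_pass_sanity_floor(separated_cohort):
    """On well-separated 3-class data every tree family clears 90%."""
    table, y = separated_cohort
    tr, te = hp.stratified_split(table, y, hp.SplitSpec(seed=3))
    x = table.values
    for fam in ("rf", "xgb", "lgbm"):
        accs = []
        for seed in range(3):
            pred, _ = hp.native_fit_predict(
                hp.LearnerSpec(fam, seed=seed), x[tr], y.labels[tr], x[te])
            accs.append((pred == y.labels[te]).mean())
        assert np.mean(accs) >= 0.9, fam


def test_events_per_predictor():
    assert hp.events_per_predictor(854, 1, 464 / 854, 25) == pytest.approx(18.56)
    with pytest.raises(ValueError):
        hp.events_per_predictor(100, 1, 0.5, 0)
    with pytest.raises(ValueError):
        hp.events_per_predictor(100, 1, 1.5, 10)
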