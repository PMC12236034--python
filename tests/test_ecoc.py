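"""Code matrices, decoding oracles, binary reduction, learner registry."""

import itertools

import numpy as np
import pytest

import hbpredict as hp
from hbpredict.ecoc import CodeMatrix


def brute_force_decode(matrix, classes, codeword):
    """Independent oracle: scan every class row, track the minimum Hamming
    distance, resolve ties to the lowest class index."""
    best, best_d = None, None
    for ci, row in enumerate(matrix):
        d = sum(int(a != b) for a, b in zip(codeword, row))
        if best_d is None or d < best_d:
            best, best_d = classes[ci], d
    return best


def test_exhaustive_code_c3():
    cm = hp.build_code_matrix(3)
    assert cm.matrix.shape == (3, 3)
    # rows match the canonical bipartition enumeration up to column order
    assert sorted(map(tuple, cm.matrix.T.tolist())) == \
        sorted([(0, 1, 0), (0, 0, 1), (0, 1, 1)])


def test_exhaustive_code_c2_single_column():
    cm = hp.build_code_matrix(2)
    assert cm.matrix.shape == (2, 1)


@pytest.mark.parametrize("bad", [
    [[0, 0], [0, 0]],          # duplicate rows
    [[0, 1], [0, 0]],          # constant column
    [[0, 1, 0], [1, 0, 1]],    # complementary columns 0/1 plus dup 0/2
])
def test_code_matrix_invariants_rejected(bad):
    with pytest.raises(hp.ConfigurationError):
        CodeMatrix(np.array(bad), [0, 1], "manual")


def test_random_dense_code_valid():
    cm = hp.build_code_matrix(5, scheme="random_dense", n_bits=10, seed=0)
    assert cm.matrix.shape == (5, 10)  # validation ran in the constructor


@pytest.mark.parametrize("n_classes", [2, 3, 4])
def test_decode_matches_brute_force_over_all_codewords(n_classes):
    """Exhaustive-code decoding equals nearest-codeword search for every
    possible M-bit codeword."""
    cm = hp.build_code_matrix(n_classes)
    m = cm.n_bits
    for bits in itertools.product((0, 1), repeat=m):
        got = hp.decode_hard(cm, np.array([bits]))[0]
        assert got == brute_force_decode(cm.matrix, cm.classes, bits)


def test_decode_tie_example():
    """Codeword (1,1,1) is Hamming-1 from both class 1 and class 2 rows;
    the tie resolves deterministically to the lower class."""
    cm = hp.build_code_matrix(3)
    rows = {tuple(r): c for c, r in zip(cm.classes, cm.matrix.tolist())}
    dists = {c: sum(int(a != b) for a, b in zip((1, 1, 1), r))
             for r, c in rows.items()}
    tied = sorted(c for c, d in dists.items() if d == min(dists.values()))
    assert hp.decode_hard(cm, np.array([[1, 1, 1]]))[0] == tied[0]


@pytest.fixture(scope="module")
def three_class_data():
    cfg = hp.GeneratorConfig(n_samples=240, n_features_per_tier=(6, 6, 6),
                             class_mix=(1 / 3, 1 / 3, 1 / 3), class_sep=4.0,
                             seed=13)
    table, y = hp.generate_cohort(cfg)
    return table.values, y.labels


def test_ecoc_fit_bit_count(three_class_data):
    x, y = three_class_data
    model = hp.ecoc_fit(hp.LearnerSpec("rf", seed=0), x, y)
    assert len(model.bit_models) == 3


def test_ecoc_scores_rank_consistent_with_decoding(three_class_data):
    x, y = three_class_data
    model = hp.ecoc_fit(hp.LearnerSpec("rf", seed=0), x, y)
    pred, scores = hp.ecoc_predict(model, x)
    assert np.array_equal(pred, np.array(model.code.classes)[
        np.argmax(scores, axis=1)])


def test_ecoc_refit_deterministic(three_class_data):
    x, y = three_class_data
    p1, s1 = hp.ecoc_predict(hp.ecoc_fit(hp.LearnerSpec("xgb", seed=1), x, y), x)
    p2, s2 = hp.ecoc_predict(hp.ecoc_fit(hp.LearnerSpec("xgb", seed=1), x, y), x)
    assert np.array_equal(p1, p2)
    assert np.allclose(s1, s2)


@pytest.mark.parametrize("family", ["rf", "linsvc"])
def test_binary_ecoc_equals_native(family, three_class_data):
    """With two classes the single-bit ECOC model is the base learner."""
    x, y = three_class_data
    keep = y < 2
    xb, yb = x[keep], y[keep]
    tr, te = np.arange(0, xb.shape[0], 2), np.arange(1, xb.shape[0], 2)
    spec = hp.LearnerSpec(family, seed=0)
    model = hp.ecoc_fit(spec, xb[tr], yb[tr])
    pred_ecoc, _ = hp.ecoc_predict(model, xb[te])
    pred_native, _ = hp.native_fit_predict(spec, xb[tr], yb[tr], xb[te])
    assert np.array_equal(pred_ecoc, pred_native)


def test_native_multiclass_trees_give_probabilities(three_class_data):
    x, y = three_class_data
    pred, scores = hp.native_fit_predict(hp.LearnerSpec("rf", seed=0),
                                         x[:200], y[:200], x[200:])
    assert scores.shape == (40, 3)
    assert np.allclose(scores.sum(axis=1), 1.0)


def test_native_svm_multiclass_rejected(three_class_data):
    x, y = three_class_data
    for family in ("linsvc", "polysvm"):
        with pytest.raises(hp.ConfigurationError):
            hp.native_fit_predict(hp.LearnerSpec(family), x, y, x)


def test_ecoc_linear_svc_separable_accuracy():
    """On linearly separable 3-class blobs the ECOC-wrapped linear
    classifier is essentially perfect."""
    from sklearn.datasets import make_blobs
    accs = []
    for seed in range(5):
        x, y = make_blobs(n_samples=240, centers=[[0, 0], [10, 0], [0, 10]],
                          cluster_std=1.0, random_state=seed)
        tr, te = np.arange(180), np.arange(180, 240)
        model = hp.ecoc_fit(hp.LearnerSpec("linsvc", seed=seed), x[tr], y[tr])
        pred, _ = hp.ecoc_predict(model, x[te])
        accs.append((pred == y[te]).mean())
    assert np.mean(accs) >= 0.95


def test_unknown_family_rejected():
    with pytest.raises(hp.ConfigurationError):
        hp.LearnerSpec("mlp")
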