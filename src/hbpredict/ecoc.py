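"""Error-correcting output codes (ECOC) over interchangeable base learners.

ECOC represents each of C classes as an M-bit binary codeword.  Training
relabels the data per bit and fits one binary model per column; prediction
collects the M bit decisions into a codeword and returns the class whose
codeword is nearest in Hamming distance.  This lets strictly binary
classifiers (the max-margin families) solve multiclass problems, and acts as
an ensemble-style wrapper around natively multiclass tree models.

Decoding ties are broken by the soft distance between the per-bit probability
vector and the class codeword, then by the lowest class index; the per-class
score combines both terms so that the score ranking always agrees with the
decoded label while remaining continuous enough for ROC analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from xgboost import XGBClassifier

from .cohort import FeatureTable, LabelVector
from .errors import ConfigurationError

__all__ = [
    "CodeMatrix", "LearnerSpec", "EcocModel", "build_code_matrix",
    "decode_hard", "ecoc_fit", "ecoc_predict", "native_fit_predict",
    "LEARNER_FAMILIES",
]


def _rf(params, seed):
    kw = {"n_estimators": 200, "n_jobs": 1, **params}
    return RandomForestClassifier(random_state=seed, **kw)


def _xgb(params, seed):
    kw = {"n_estimators": 100, "max_depth": 4, "learning_rate": 0.3,
          "tree_method": "hist", "n_jobs": 1, "verbosity": 0, **params}
    return XGBClassifier(random_state=seed, **kw)


def _lgbm(params, seed):
    kw = {"n_estimators": 100, "n_jobs": 1, "verbose": -1, **params}
    return LGBMClassifier(random_state=seed, **kw)


def _linsvc(params, seed):
    return Pipeline([("scale", StandardScaler()),
                     ("svc", LinearSVC(random_state=seed, **params))])


def _polysvm(params, seed):
    kw = {"kernel": "poly", "degree": 3, **params}
    return Pipeline([("scale", StandardScaler()),
                     ("svc", SVC(random_state=seed, **kw))])


#: the five base learner families; the max-margin two are binary-only
LEARNER_FAMILIES = {
    "rf": {"build": _rf, "multiclass": True},
    "xgb": {"build": _xgb, "multiclass": True},
    "lgbm": {"build": _lgbm, "multiclass": True},
    "linsvc": {"build": _linsvc, "multiclass": False},
    "polysvm": {"build": _polysvm, "multiclass": False},
}


@dataclass(frozen=True)
class LearnerSpec:
    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in LEARNER_FAMILIES:
            raise ConfigurationError(f"unknown learner family {self.family!r}")

    def build(self):
        return LEARNER_FAMILIES[self.family]["build"](dict(self.params),
                                                      self.seed)

    @property
    def native_multiclass(self) -> bool:
        return LEARNER_FAMILIES[self.family]["multiclass"]


@dataclass
class CodeMatrix:
    """Classes x bits binary codebook."""

    matrix: np.ndarray
    classes: list
    scheme: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=int)
        self.validate()

    @property
    def n_bits(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        c, m = self.matrix.shape
        if not np.isin(self.matrix, (0, 1)).all():
            raise ConfigurationError("code matrix entries must be 0/1")
        if m < math.ceil(math.log2(max(c, 2))):
            raise ConfigurationError("too few bits to separate the classes")
        if len({tuple(r) for r in self.matrix}) != c:
            raise ConfigurationError("code matrix rows must be distinct")
        for j in range(m):
            col = self.matrix[:, j]
            if col.min() == col.max():
                raise ConfigurationError(f"column {j} is constant")
        for i in range(m):
            for j in range(i + 1, m):
                same = (self.matrix[:, i] == self.matrix[:, j]).all()
                compl = (self.matrix[:, i] == 1 - self.matrix[:, j]).all()
                if same or compl:
                    raise ConfigurationError(
                        f"columns {i} and {j} are identical or complementary")


def build_code_matrix(n_classes: int, scheme: str = "exhaustive",
                      n_bits: int | None = None, seed: int = 0) -> CodeMatrix:
    """Construct a valid codebook.

    ``exhaustive`` enumerates every non-degenerate bipartition up to
    complement (M = 2^(C-1) - 1 columns).  ``random_dense`` samples candidate
    matrices and keeps the valid one with the largest minimum pairwise row
    Hamming distance.
    """
    if n_classes < 2:
        raise ConfigurationError("need at least two classes")
    classes = list(range(n_classes))
    if scheme == "exhaustive":
        cols = []
        for mask in range(1, 2 ** (n_classes - 1)):
            col = [(mask >> (c - 1)) & 1 if c > 0 else 0
                   for c in range(n_classes)]
            cols.append(col)
        matrix = np.array(cols).T
        return CodeMatrix(matrix, classes, "exhaustive")
    if scheme != "random_dense":
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    if n_bits is None:
        n_bits = max(math.ceil(10 * math.log2(n_classes)), 3)
    if n_bits < math.ceil(math.log2(n_classes)):
        raise ConfigurationError("n_bits below log2(n_classes)")
    rng = np.random.default_rng(seed)
    best, best_sep = None, -1
    for _ in range(200):
        cand = rng.integers(0, 2, size=(n_classes, n_bits))
        try:
            cm = CodeMatrix(cand, classes, "random_dense")
        except ConfigurationError:
            continue
        sep = min(np.sum(cand[i] != cand[j])
                  for i in range(n_classes) for j in range(i + 1, n_classes))
        if sep > best_sep:
            best, best_sep = cm, sep
    if best is None:
        raise ConfigurationError(
            f"could not sample a valid {n_classes}x{n_bits} code matrix")
    return best


def decode_hard(code: CodeMatrix, bits: np.ndarray) -> np.ndarray:
    """Minimum-Hamming-distance decoding; ties go to the lowest class index."""
    bits = np.atleast_2d(np.asarray(bits, dtype=int))
    ham = np.abs(bits[:, None, :] - code.matrix[None]).sum(axis=2)
    return np.array([code.classes[i] for i in np.argmin(ham, axis=1)])


@dataclass
class EcocModel:
    code: CodeMatrix
    bit_models: list
    spec: LearnerSpec
    n_features: int

    def __post_init__(self):
        if len(self.bit_models) != self.code.n_bits:
            raise ConfigurationError("bit model count must equal code width")


def _as_xy(table, labels):
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    return x, y


def ecoc_fit(spec: LearnerSpec, table, labels,
             code: CodeMatrix | None = None) -> EcocModel:
    """Train one binary model per code column on the relabeled data."""
    x, y = _as_xy(table, labels)
    classes = sorted(np.unique(y).tolist())
    if code is None:
        code = build_code_matrix(len(classes), "exhaustive")
        code = CodeMatrix(code.matrix, classes, code.scheme)
    if not set(classes) <= set(code.classes):
        raise ConfigurationError("labels outside the code matrix class set")
    class_row = {c: i for i, c in enumerate(code.classes)}
    row_idx = np.array([class_row[c] for c in y])
    models = []
    for m in range(code.n_bits):
        y_bit = code.matrix[row_idx, m]
        if np.unique(y_bit).size < 2:
            raise RuntimeError(f"bit {m} degenerates to a single class")
        model = clone(spec.build())
        model.fit(x, y_bit)
        models.append(model)
    return EcocModel(code, models, spec, x.shape[1])


def _bit_probabilities(model, x) -> np.ndarray:
    """P(bit = 1) per row, from predict_proba or a squashed margin."""
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(x)
            one = list(model.classes_).index(1)
            return proba[:, one]
        except AttributeError:
            pass
    margin = model.decision_function(x)
    return 1.0 / (1.0 + np.exp(-margin))


def ecoc_predict(model: EcocModel, rows) -> tuple[np.ndarray, np.ndarray]:
    """Decode per-row bit predictions to labels and per-class scores.

    The label minimizes (Hamming distance, soft distance, class index)
    lexicographically.  The returned score is
    ``-(hamming + soft / (sqrt(M) + 1))`` so that argmax(score) equals the
    decoded label on every row while the scores stay continuous for ROC
    analysis.
    """
    x = rows.values if isinstance(rows, FeatureTable) else np.asarray(rows)
    if x.shape[1] != model.n_features:
        raise ValueError("row dimensionality mismatch")
    bits = np.column_stack([m.predict(x) for m in model.bit_models]).astype(int)
    probs = np.column_stack([_bit_probabilities(m, x)
                             for m in model.bit_models])
    code = model.code.matrix
    ham = np.abs(bits[:, None, :] - code[None]).sum(axis=2)
    soft = np.linalg.norm(probs[:, None, :] - code[None], axis=2)
    scores = -(ham + soft / (math.sqrt(model.code.n_bits) + 1.0))
    labels = np.array([model.code.classes[i] for i in np.argmax(scores, axis=1)])
    return labels, scores


def native_fit_predict(spec: LearnerSpec, x_train, y_train,
                       x_test) -> tuple[np.ndarray, np.ndarray]:
    """Un-wrapped baseline: the base learner's own multiclass fit/predict.

    Max-margin families are binary-only, so more than two classes without
    ECOC is a configuration error.
    """
    x_train, y_train = _as_xy(x_train, y_train)
    x_test = (x_test.values if isinstance(x_test, FeatureTable)
              else np.asarray(x_test))
    classes = sorted(np.unique(y_train).tolist())
    if len(classes) > 2 and not spec.native_multiclass:
        raise ConfigurationError(
            f"{spec.family} is binary-only; wrap it with ECOC for "
            f"{len(classes)}-class problems")
    model = spec.build()
    model.fit(x_train, y_train)
    pred = model.predict(x_test)
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(x_test)
    else:
        margin = model.decision_function(x_test)
        if margin.ndim == 1:
            p1 = 1.0 / (1.0 + np.exp(-margin))
            scores = np.column_stack([1 - p1, p1])
        else:
            scores = margin
    return pred, scores
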