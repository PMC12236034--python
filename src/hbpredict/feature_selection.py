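"""Feature screening: boosted-tree importance, RFE, and a LASSO cross-check.

Importance comes from a gradient-boosted tree ensemble (total gain per
feature, normalized to sum to one).  Recursive feature elimination repeatedly
drops the least important features, tracking stratified-CV accuracy, and
retains the smallest subset whose accuracy stays within a relative tolerance
of the full-feature accuracy.  An L1-regularized logistic path over a
binarized outcome serves as a qualitative cross-check of the retained set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from xgboost import XGBClassifier

from .cohort import FeatureTable, LabelVector
from .errors import ConfigurationError

__all__ = [
    "ImportanceReport", "SelectionResult",
    "rank_importance", "rfe_select", "compare_importance", "lasso_crosscheck",
]

_XGB_DEFAULTS = dict(n_estimators=100, max_depth=4, learning_rate=0.3,
                     tree_method="hist", n_jobs=1, verbosity=0)


@dataclass
class ImportanceReport:
    """Descending (feature, score) pairs; scores are normalized total gain."""

    scores: list[tuple[str, float]]
    model_params: dict = field(default_factory=dict)
    data_fingerprint: tuple[int, int] = (0, 0)

    def as_dict(self) -> dict[str, float]:
        return dict(self.scores)

    @property
    def ranking(self) -> list[str]:
        return [f for f, _ in self.scores]


@dataclass
class SelectionResult:
    retained: list[str]
    n_retained: int
    accuracy_curve: list[tuple[int, float]]
    full_accuracy: float
    relative_loss: float


def _as_xy(table, labels):
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    return x, y


def _encode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, enc = np.unique(y, return_inverse=True)
    return classes, enc


def _fit_importance(x, y_enc, names, seed, params) -> dict[str, float]:
    model = XGBClassifier(random_state=seed, **params)
    model.fit(x, y_enc)
    gain = model.get_booster().get_score(importance_type="total_gain")
    raw = np.array([gain.get(f"f{i}", 0.0) for i in range(x.shape[1])])
    total = raw.sum()
    norm = raw / total if total > 0 else np.full(raw.size, 1.0 / raw.size)
    return dict(zip(names, norm))


def rank_importance(table, labels, seed: int = 0,
                    params: dict | None = None) -> ImportanceReport:
    """Gain-based importance ranking from a boosted-tree fit.

    Scores are normalized to sum to 1; the sort is stable with ties broken
    by feature name.
    """
    x, y = _as_xy(table, labels)
    if not np.isfinite(x).all():
        raise ValueError("table contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("at least two classes are required")
    names = (table.feature_names if isinstance(table, FeatureTable)
             else [f"x{i}" for i in range(x.shape[1])])
    merged = {**_XGB_DEFAULTS, **(params or {})}
    _, y_enc = _encode(y)
    scores = _fit_importance(x, y_enc, names, seed, merged)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ImportanceReport(ordered, {**merged, "seed": seed}, x.shape)


def _cv_accuracy(x, y_enc, seed, cv, params) -> float:
    model = XGBClassifier(random_state=seed, **params)
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    return float(cross_val_score(model, x, y_enc, cv=folds,
                                 scoring="accuracy").mean())


def rfe_select(table, labels, tolerance: float = 0.001, step: int = 1,
               seed: int = 0, cv: int = 5,
               params: dict | None = None) -> SelectionResult:
    """Recursive feature elimination with an accuracy-loss tolerance.

    At each stage the ``step`` lowest-importance features are dropped and
    stratified-CV accuracy is recorded; the retained set is the smallest
    visited subset whose accuracy is >= (1 - tolerance) * full accuracy.
    """
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    if step < 1:
        raise ConfigurationError("step must be >= 1")
    x, y = _as_xy(table, labels)
    names = (table.feature_names if isinstance(table, FeatureTable)
             else [f"x{i}" for i in range(x.shape[1])])
    merged = {**_XGB_DEFAULTS, **(params or {})}
    _, y_enc = _encode(y)

    current = list(names)
    curve: list[tuple[int, float]] = []
    subsets: dict[int, list[str]] = {}
    while True:
        idx = [names.index(f) for f in current]
        acc = _cv_accuracy(x[:, idx], y_enc, seed, cv, merged)
        curve.append((len(current), acc))
        subsets[len(current)] = list(current)
        if len(current) == 1:
            break
        imp = _fit_importance(x[:, idx], y_enc, current, seed, merged)
        ordered = sorted(imp.items(), key=lambda kv: (kv[1], kv[0]))
        drop = {f for f, _ in ordered[:min(step, len(current) - 1)]}
        current = [f for f in current if f not in drop]

    full_acc = curve[0][1]
    threshold = (1.0 - tolerance) * full_acc
    qualifying = [n for n, a in curve if a >= threshold]
    if not qualifying:
        warnings.warn("no subset met the tolerance; returning the full set")
        n_keep = len(names)
    else:
        n_keep = min(qualifying)
    keep_acc = dict(curve)[n_keep]
    retained = subsets[n_keep]
    imp_final = rank_importance(x[:, [names.index(f) for f in retained]],
                                y, seed=seed, params=params)
    ordered_retained = [retained[int(f[1:])] for f in imp_final.ranking]
    loss = (full_acc - keep_acc) / full_acc if full_acc > 0 else 0.0
    return SelectionResult(ordered_retained, n_keep, curve, full_acc, loss)


def compare_importance(before: ImportanceReport,
                       after: ImportanceReport) -> dict:
    """Per-feature score deltas, rank displacement, and a rank correlation."""
    fb, fa = set(before.as_dict()), set(after.as_dict())
    if fb != fa:
        raise ValueError("importance reports cover different feature sets")
    feats = sorted(fb)
    b, a = before.as_dict(), after.as_dict()
    rank_b = {f: i for i, f in enumerate(before.ranking)}
    rank_a = {f: i for i, f in enumerate(after.ranking)}
    deltas = {f: a[f] - b[f] for f in feats}
    displacement = {f: rank_a[f] - rank_b[f] for f in feats}
    if len(feats) > 1:
        rho = float(spearmanr([rank_b[f] for f in feats],
                              [rank_a[f] for f in feats]).statistic)
    else:
        rho = 1.0
    return {"deltas": deltas, "rank_displacement": displacement,
            "rank_correlation": rho}


def lasso_crosscheck(table, labels_binary, penalties=None, seed: int = 0,
                     cv: int = 5) -> dict:
    """L1-logistic path over a binary outcome for qualitative validation.

    Returns per-penalty selected feature sets and CV AUCs, plus the selected
    set at the AUC-maximizing penalty.  Penalties are inverse regularization
    strengths (sklearn's C): small C means heavy shrinkage.
    """
    x, y = _as_xy(table, labels_binary)
    if np.unique(y).size != 2:
        raise ValueError("labels must be binary for the LASSO cross-check")
    names = (table.feature_names if isinstance(table, FeatureTable)
             else [f"x{i}" for i in range(x.shape[1])])
    if penalties is None:
        penalties = np.logspace(-3, 2, 11)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - mean) / sd
    path = []
    for c in penalties:
        model = LogisticRegression(penalty="l1", solver="liblinear",
                                   C=float(c), random_state=seed, max_iter=500)
        folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc = float(cross_val_score(model, xz, y, cv=folds,
                                        scoring="roc_auc").mean())
            model.fit(xz, y)
        selected = [names[i] for i in np.flatnonzero(model.coef_[0] != 0)]
        path.append({"penalty": float(c), "auc": auc, "selected": selected})
    best = max(path, key=lambda rec: rec["auc"])
    return {"path": path, "best_penalty": best["penalty"],
            "selected": best["selected"]}
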