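"""Splitting, stratified cross-validation, and the classification metric stack.

Reports carry accuracy, macro and support-weighted precision/recall/F1,
micro-averaged one-vs-rest ROC AUC, per-class rows, and the confusion
matrix.  Cross-validation aggregates per-fold reports, including the
elementwise mean confusion matrix.  An events-per-predictor helper provides
the conventional sample-size adequacy check for clinical prediction models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .cohort import FeatureTable, LabelVector
from .ecoc import CodeMatrix, LearnerSpec, ecoc_fit, ecoc_predict, \
    native_fit_predict
from .errors import ConfigurationError

__all__ = [
    "SplitSpec", "EvaluationReport", "CvResult", "stratified_split",
    "compute_metrics", "cross_validate", "compare_models",
    "events_per_predictor",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


@dataclass
class EvaluationReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    micro_auc: float | None
    per_class: list[dict]
    confusion: np.ndarray
    n: int

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "macro_precision", "macro_recall", "macro_f1",
              "weighted_precision", "weighted_recall", "weighted_f1",
              "micro_auc", "n")}
        d["per_class"] = self.per_class
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d


@dataclass
class CvResult:
    fold_reports: list[EvaluationReport]
    mean_report: EvaluationReport
    mean_confusion: np.ndarray


def _as_xy(table, labels):
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    return x, y


def stratified_split(table, labels, spec: SplitSpec | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into train/test index arrays.

    Each class contributes round(fraction * n_c) training samples (clamped so
    both sides are nonempty); a singleton class goes to train with a warning.
    """
    spec = spec or SplitSpec()
    _, y = _as_xy(table, labels)
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    if not spec.stratified:
        perm = rng.permutation(y.size)
        cut = int(round(spec.train_fraction * y.size))
        return np.sort(perm[:cut]), np.sort(perm[cut:])
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size == 1:
            warnings.warn(f"class {c} has a single member; assigned to train")
            train_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(round(spec.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)))


def compute_metrics(y_true, y_pred, scores: np.ndarray | None = None,
                    classes: np.ndarray | None = None) -> EvaluationReport:
    """Full metric stack for one evaluation.

    ``scores`` (one column per class, aligned with ``classes``) enables the
    micro-averaged one-vs-rest ROC AUC: the one-hot true matrix and the score
    matrix are flattened and a single ROC curve is computed.  Classes never
    predicted get precision 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction length mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)

    missing_pred = set(np.unique(y_true)) - set(np.unique(y_pred))
    if missing_pred:
        warnings.warn(
            f"classes never predicted (precision set to 0): {sorted(missing_pred)}")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    w = support / support.sum()
    per_class = [
        {"label": int(c), "precision": float(p), "recall": float(r),
         "f1": float(f), "support": int(s)}
        for c, p, r, f, s in zip(classes, prec, rec, f1, support)]

    micro_auc = None
    if scores is not None:
        scores = np.asarray(scores)
        if scores.shape != (y_true.size, classes.size):
            raise ValueError("scores must be one column per class")
        onehot = (y_true[:, None] == classes[None]).astype(int)
        micro_auc = float(roc_auc_score(onehot.ravel(), scores.ravel()))

    return EvaluationReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float((prec * w).sum()),
        weighted_recall=float((rec * w).sum()),
        weighted_f1=float((f1 * w).sum()),
        micro_auc=micro_auc,
        per_class=per_class,
        confusion=confusion_matrix(y_true, y_pred, labels=classes).astype(float),
        n=int(y_true.size),
    )


def _mean_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    conf = np.mean([r.confusion for r in reports], axis=0)
    labels = [pc["label"] for pc in reports[0].per_class]
    per_class = []
    for i, lab in enumerate(labels):
        per_class.append({
            "label": lab,
            "precision": float(np.mean([r.per_class[i]["precision"] for r in reports])),
            "recall": float(np.mean([r.per_class[i]["recall"] for r in reports])),
            "f1": float(np.mean([r.per_class[i]["f1"] for r in reports])),
            "support": int(np.sum([r.per_class[i]["support"] for r in reports])),
        })
    aucs = [r.micro_auc for r in reports if r.micro_auc is not None]
    return EvaluationReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        macro_precision=float(np.mean([r.macro_precision for r in reports])),
        macro_recall=float(np.mean([r.macro_recall for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        weighted_precision=float(np.mean([r.weighted_precision for r in reports])),
        weighted_recall=float(np.mean([r.weighted_recall for r in reports])),
        weighted_f1=float(np.mean([r.weighted_f1 for r in reports])),
        micro_auc=float(np.mean(aucs)) if aucs else None,
        per_class=per_class,
        confusion=conf,
        n=int(np.sum([r.n for r in reports])),
    )


def cross_validate(spec: LearnerSpec, ecoc: bool, table, labels,
                   folds: int = 10, seed: int = 0,
                   code: CodeMatrix | None = None) -> CvResult:
    """Stratified k-fold CV of one (learner, ECOC flag) combination."""
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    x, y = _as_xy(table, labels)
    min_class = np.unique(y, return_counts=True)[1].min()
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} members; "
                      f"reducing folds from {folds}")
        folds = max(2, int(min_class))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    reports = []
    for train, test in skf.split(x, y):
        if ecoc:
            model = ecoc_fit(spec, x[train], y[train], code=code)
            pred, scores = ecoc_predict(model, x[test])
        else:
            pred, scores = native_fit_predict(spec, x[train], y[train], x[test])
        reports.append(compute_metrics(y[test], pred, scores, classes))
    mean = _mean_reports(reports)
    return CvResult(reports, mean, mean.confusion)


def compare_models(specs: list[tuple[LearnerSpec, bool]], x_train, y_train,
                   x_test, y_test, code: CodeMatrix | None = None) -> dict:
    """Side-by-side test-set metrics without (A) and with (B) ECOC.

    Each entry is (spec, native_supported); tree families get both columns,
    binary-only families the ECOC column alone.  Deltas are B - A.
    """
    if not specs:
        raise ValueError("at least one learner spec is required")
    x_train, y_train = _as_xy(x_train, y_train)
    x_test, y_test = _as_xy(x_test, y_test)
    classes = np.unique(np.concatenate([y_train, y_test]))
    rows = []
    for spec, with_native in specs:
        entry: dict = {"family": spec.family}
        if with_native and (spec.native_multiclass or classes.size == 2):
            pred, scores = native_fit_predict(spec, x_train, y_train, x_test)
            entry["native"] = compute_metrics(y_test, pred, scores,
                                              classes).as_dict()
        model = ecoc_fit(spec, x_train, y_train, code=code)
        pred, scores = ecoc_predict(model, x_test)
        entry["ecoc"] = compute_metrics(y_test, pred, scores,
                                        classes).as_dict()
        if "native" in entry:
            entry["delta"] = {
                k: entry["ecoc"][k] - entry["native"][k]
                for k in ("accuracy", "macro_f1", "micro_auc")
                if entry["ecoc"][k] is not None and entry["native"][k] is not None}
        rows.append(entry)
    return {"classes": classes.tolist(), "models": rows,
            "markdown": _models_markdown(rows)}


def _models_markdown(rows: list[dict]) -> str:
    lines = ["| model | acc A | acc B | B-A | macro-F1 A | macro-F1 B | "
             "micro-AUC A | micro-AUC B |",
             "|---|---|---|---|---|---|---|---|"]
    for r in rows:
        a = r.get("native")
        b = r["ecoc"]
        fmt = lambda rep, k: f"{rep[k]:.4f}" if rep and rep.get(k) is not None else "-"
        delta = (f"{r['delta']['accuracy']:+.4f}" if "delta" in r else "-")
        lines.append(
            f"| {r['family']} | {fmt(a, 'accuracy')} | {fmt(b, 'accuracy')} "
            f"| {delta} | {fmt(a, 'macro_f1')} | {fmt(b, 'macro_f1')} "
            f"| {fmt(a, 'micro_auc')} | {fmt(b, 'micro_auc')} |")
    return "\n".join(lines)


def events_per_predictor(n_patients: int, follow_up_years: float,
                         event_rate: float, n_predictors: int) -> float:
    """Events per predictor (EPP): n * years * event rate / predictors.

    The conventional adequacy floor for clinical prediction models is 10.
    """
    if n_predictors <= 0:
        raise ValueError("n_predictors must be positive")
    if not 0.0 <= event_rate <= 1.0:
        raise ValueError("event_rate must lie in [0, 1]")
    return n_patients * follow_up_years * event_rate / n_predictors
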