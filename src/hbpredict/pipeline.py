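"""End-to-end orchestration and cohort file IO.

The pipeline runs the stages in their canonical order — generate/load,
impute, split, balance (training partition only by default, to avoid
leakage), screen features, choose the class count, train with and without
ECOC, evaluate — persisting every intermediate table as CSV and recording a
manifest with per-stage fingerprints so a run is auditable and reproducible
from its config and seed.

Cohort files are plain CSV: a values table (missing cells empty), a
feature-metadata sidecar (name, tier, kind), and a labels file (label and
optionally haemoglobin).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .balancing import BalanceConfig, adasyn, class_distribution
from .class_count import best_approximation
from .cohort import (FeatureMeta, FeatureTable, GeneratorConfig, LabelVector,
                     MissingnessTier, generate_cohort,
                     inject_tiered_missingness)
from .ecoc import LearnerSpec
from .errors import ConfigurationError, FormatError, PipelineStageError
from .evaluation import (SplitSpec, compare_models, cross_validate,
                         stratified_split)
from .feature_selection import rfe_select
from .imputation import fused_fill, knn_fill, mean_fill

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "read_cohort", "write_cohort"]

_TIER_BY_NAME = {t.value: t for t in MissingnessTier}


def _version() -> str:
    from . import __version__
    return __version__


def write_cohort(table: FeatureTable, outdir, labels: LabelVector | None = None,
                 prefix: str = "cohort") -> dict[str, str]:
    """Write values/meta/labels CSVs; missing cells are left empty."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vals = pd.DataFrame(table.values, columns=table.feature_names)
    vals = vals.mask(pd.DataFrame(table.mask, columns=table.feature_names))
    paths = {"values": str(outdir / f"{prefix}.csv"),
             "meta": str(outdir / f"{prefix}_features.csv")}
    vals.to_csv(paths["values"], index=False)
    pd.DataFrame(
        {"name": [m.name for m in table.meta],
         "tier": [m.tier.value for m in table.meta],
         "kind": [m.kind for m in table.meta]}
    ).to_csv(paths["meta"], index=False)
    if labels is not None:
        ldf = pd.DataFrame({"label": labels.labels})
        if labels.source_hb is not None:
            ldf["hb"] = labels.source_hb
        paths["labels"] = str(outdir / f"{prefix}_labels.csv")
        ldf.to_csv(paths["labels"], index=False)
    return paths


def _check_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col].map(
                lambda v: isinstance(v, str) and not _is_number(v))
            if bad.any():
                # +2: header row and 1-based indexing
                line = int(np.flatnonzero(bad.values)[0]) + 2
                raise FormatError(
                    f"{path}: non-numeric value in column {col!r} "
                    f"at line {line}")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_cohort(values_path, meta_path, labels_path=None
                ) -> tuple[FeatureTable, LabelVector | None]:
    """Read a cohort written by :func:`write_cohort` (lossless round-trip)."""
    values_path, meta_path = Path(values_path), Path(meta_path)
    if not meta_path.exists():
        raise FormatError(f"feature metadata sidecar not found: {meta_path}")
    df = pd.read_csv(values_path)
    _check_numeric(df, values_path)
    meta_df = pd.read_csv(meta_path)
    meta = []
    for i, rec in meta_df.iterrows():
        if rec["tier"] not in _TIER_BY_NAME:
            raise FormatError(
                f"{meta_path}: unknown tier {rec['tier']!r} at line {i + 2}")
        if rec["kind"] not in ("continuous", "categorical"):
            raise FormatError(
                f"{meta_path}: unknown kind {rec['kind']!r} at line {i + 2}")
        meta.append(FeatureMeta(rec["name"], _TIER_BY_NAME[rec["tier"]],
                                rec["kind"]))
    if list(df.columns) != [m.name for m in meta]:
        raise FormatError("values header does not match metadata sidecar")
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    values = np.where(mask, 0.0, values)
    table = FeatureTable(values, mask, meta)
    labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path)
        hb = ldf["hb"].to_numpy() if "hb" in ldf.columns else None
        labels = LabelVector(ldf["label"].to_numpy(dtype=int), hb)
    return table, labels


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full run."""

    seed: int = 0
    outdir: str = "runs/run"
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    input_paths: dict | None = None          # values/meta/labels; used when generator is None
    missingness_rates: tuple[float, float, float] | None = (0.0, 0.05, 0.25)
    impute_method: str = "fused"             # fused | knn | mean | none
    knn_k: int = 5
    balance: bool = True
    balance_train_only: bool = True          # leakage-safe default
    balance_strategy: str = "not_majority"
    balance_beta: float = 1.0
    select_features: bool = True
    rfe_tolerance: float = 0.001
    rfe_step: int = 5
    class_count_candidates: tuple[int, ...] | None = (2, 3, 4)
    models: tuple[str, ...] = ("rf", "xgb", "lgbm", "linsvc", "polysvm")
    train_fraction: float = 0.8
    cv_folds: int = 10
    run_cv: bool = False

    def __post_init__(self):
        if self.generator is None and not self.input_paths:
            raise ConfigurationError("either a generator config or input "
                                     "paths must be provided")
        if self.impute_method not in ("fused", "knn", "mean", "none"):
            raise ConfigurationError(
                f"unknown impute method {self.impute_method!r}")


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def fingerprints(self) -> dict:
        return {s["stage"]: s.get("fingerprint") for s in self.stages}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "artifacts": self.artifacts, "versions": self.versions},
            indent=2, default=str))


def _fingerprint(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        versions={"hbpredict": _version(), "numpy": np.__version__,
                  "pandas": pd.__version__})
    manifest_path = outdir / "manifest.json"

    def stage(name):
        rec = {"stage": name, "start": time.time()}
        manifest.stages.append(rec)
        return rec

    def fail(name, exc):
        manifest.stages[-1]["error"] = repr(exc)
        manifest.save(manifest_path)
        raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc

    # --- data -------------------------------------------------------------
    rec = stage("data")
    try:
        if config.generator is not None:
            gen = GeneratorConfig(**{**asdict(config.generator),
                                     "seed": config.generator.seed})
            table, labels = generate_cohort(gen)
            if config.missingness_rates is not None:
                table = inject_tiered_missingness(
                    table, config.missingness_rates, seed=config.seed)
        else:
            table, labels = read_cohort(**config.input_paths)
            if labels is None:
                raise ConfigurationError("labels are required for a full run")
        manifest.artifacts.update(write_cohort(table, outdir, labels, "input"))
        rec["fingerprint"] = _fingerprint(table.values, table.mask, labels.labels)
        rec["shape"] = list(table.values.shape)
        rec["class_counts"] = class_distribution(labels)["counts"]
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail("data", exc)

    # --- imputation -------------------------------------------------------
    rec = stage("impute")
    try:
        if config.impute_method == "none":
            filled = table
        else:
            fillers = {"fused": lambda t: fused_fill(t),
                       "knn": lambda t: knn_fill(
                           t, features=[t.meta[j].name
                                        for j in t.fillable_columns],
                           k=config.knn_k),
                       "mean": mean_fill}
            filled = fillers[config.impute_method](table).table
        manifest.artifacts.update(write_cohort(filled, outdir, None, "filled"))
        rec["fingerprint"] = _fingerprint(filled.values)
    except Exception as exc:
        fail("impute", exc)

    # --- split ------------------------------------------------------------
    rec = stage("split")
    try:
        tr, te = stratified_split(filled, labels, SplitSpec(
            config.train_fraction, True, config.seed))
        rec["fingerprint"] = _fingerprint(tr, te)
        rec["n_train"], rec["n_test"] = int(tr.size), int(te.size)
    except Exception as exc:
        fail("split", exc)

    x, y = filled.values, labels.labels
    x_train, y_train = x[tr], y[tr]
    x_test, y_test = x[te], y[te]

    # --- balancing --------------------------------------------------------
    rec = stage("balance")
    try:
        if config.balance:
            part = FeatureTable(x_train, np.zeros_like(x_train, dtype=bool),
                                list(filled.meta))
            balanced = adasyn(part, LabelVector(y_train), BalanceConfig(
                beta=config.balance_beta, seed=config.seed,
                strategy=config.balance_strategy))
            x_train, y_train = balanced.table.values, balanced.labels.labels
            rec["counts_before"] = balanced.counts_before
            rec["counts_after"] = balanced.counts_after
        rec["fingerprint"] = _fingerprint(x_train, y_train)
    except Exception as exc:
        fail("balance", exc)

    # --- feature selection ------------------------------------------------
    rec = stage("select")
    try:
        names = filled.feature_names
        if config.select_features:
            sel = rfe_select(x_train, y_train, tolerance=config.rfe_tolerance,
                             step=config.rfe_step, seed=config.seed)
            # rfe_select saw a bare array, so retained names are "x<idx>"
            keep = sorted(int(f[1:]) for f in sel.retained)
            x_train, x_test = x_train[:, keep], x_test[:, keep]
            rec["n_retained"] = sel.n_retained
            rec["retained"] = [names[i] for i in keep]
            (outdir / "selection.json").write_text(json.dumps(
                {"retained": rec["retained"],
                 "accuracy_curve": sel.accuracy_curve,
                 "full_accuracy": sel.full_accuracy,
                 "relative_loss": sel.relative_loss}, indent=2))
            manifest.artifacts["selection"] = str(outdir / "selection.json")
        rec["fingerprint"] = _fingerprint(x_train)
    except Exception as exc:
        fail("select", exc)

    # --- class count ------------------------------------------------------
    rec = stage("class_count")
    try:
        if config.class_count_candidates and labels.source_hb is not None:
            decision = best_approximation(filled, labels,
                                          config.class_count_candidates,
                                          seed=config.seed)
            rec["chosen_k"] = decision.chosen_k
            rec["elbow_k"] = decision.elbow_k
            rec["silhouette_k"] = decision.silhouette_k
            (outdir / "classcount.json").write_text(json.dumps(
                {"chosen_k": decision.chosen_k,
                 "elbow_k": decision.elbow_k,
                 "silhouette_k": decision.silhouette_k,
                 "similarities": [asdict(s) for s in decision.similarities],
                 "rationale": decision.rationale}, indent=2))
            manifest.artifacts["classcount"] = str(outdir / "classcount.json")
    except Exception as exc:
        fail("class_count", exc)

    # --- models -----------------------------------------------------------
    rec = stage("models")
    try:
        specs = [(LearnerSpec(fam, seed=config.seed), True)
                 for fam in config.models]
        report = compare_models(specs, x_train, y_train, x_test, y_test)
        if config.run_cv:
            cv = cross_validate(LearnerSpec("xgb", seed=config.seed), True,
                                x_train, y_train, folds=config.cv_folds,
                                seed=config.seed)
            report["cv_mean"] = cv.mean_report.as_dict()
        (outdir / "eval.json").write_text(json.dumps(report, indent=2,
                                                     default=str))
        manifest.artifacts["eval"] = str(outdir / "eval.json")
        rec["fingerprint"] = _fingerprint(np.array(
            [m["ecoc"]["accuracy"] for m in report["models"]]))
    except Exception as exc:
        fail("models", exc)

    manifest.save(manifest_path)
    manifest.artifacts["manifest"] = str(manifest_path)
    return manifest
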