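"""Synthetic clinical cohorts with tiered missingness and an imbalanced outcome.

Real post-transplant cohorts are private, so the pipeline is exercised on
generated tables that reproduce the structure the downstream stages rely on:

* mixed continuous/categorical features drawn from a low-rank latent factor
  model, so features are inter-correlated and missing entries are in principle
  recoverable from observed ones;
* three missingness tiers — basic/pre-operative information that is always
  recorded, routine labs that are rarely missing, and derived or late-window
  quantities that are often missing;
* a haemoglobin (Hb, g/L) outcome thresholded at 115 and 150 g/L into
  normal (0) / low (1) / high (2) classes, with a configurable and by default
  severely imbalanced class mix.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "MissingnessTier",
    "FeatureMeta",
    "FeatureTable",
    "LabelVector",
    "GeneratorConfig",
    "generate_cohort",
    "assign_labels",
    "inject_missingness",
    "inject_tiered_missingness",
]


class MissingnessTier(enum.Enum):
    """How prone a clinical feature is to being unrecorded.

    NO_MISSING covers demographics and pre-operative examinations that are
    effectively always present; NOT_EASY covers routine in-window labs with a
    low missing probability; EASY covers derived or late-window quantities
    with a relatively high missing probability.
    """

    NO_MISSING = "no_missing"
    NOT_EASY = "not_easy"
    EASY = "easy"


@dataclass(frozen=True)
class FeatureMeta:
    name: str
    tier: MissingnessTier
    kind: str  # "continuous" | "categorical"

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")


@dataclass
class FeatureTable:
    """Samples x features matrix with an explicit missingness mask.

    ``values`` is float; categorical features are integer-coded.  ``mask``
    is True where the entry is missing — a dedicated mask rather than a
    sentinel value, so zero is a legal observation.
    """

    values: np.ndarray
    mask: np.ndarray
    meta: list[FeatureMeta]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ConfigurationError("values and mask shapes differ")
        if self.values.shape[1] != len(self.meta):
            raise ConfigurationError("meta length must equal column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    def columns_of_tier(self, tier: MissingnessTier) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.meta) if m.tier == tier],
                        dtype=int)

    @property
    def fillable_columns(self) -> np.ndarray:
        """Columns belonging to tiers that may contain missing entries."""
        return np.array(
            [i for i, m in enumerate(self.meta)
             if m.tier != MissingnessTier.NO_MISSING],
            dtype=int)

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.mask.copy(), list(self.meta))

    def validate(self) -> None:
        no_missing = self.columns_of_tier(MissingnessTier.NO_MISSING)
        if no_missing.size and self.mask[:, no_missing].any():
            raise ConfigurationError("NO_MISSING tier columns carry a mask")


@dataclass
class LabelVector:
    """Per-sample outcome class in {0,1,2}; optionally the source Hb values."""

    labels: np.ndarray
    source_hb: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1, 2)).all():
            raise ConfigurationError("labels restricted to {0, 1, 2}")
        if self.source_hb is not None:
            self.source_hb = np.asarray(self.source_hb, dtype=float)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a mid-size single-centre transplant cohort: 854 patients,
    95 features split 25/40/30 across the three missingness tiers, and a
    normal:low:high class mix of 390:447:17.
    """

    n_samples: int = 854
    n_features_per_tier: tuple[int, int, int] = (25, 40, 30)
    latent_rank: int = 6
    noise_sd: float = 0.3
    class_mix: tuple[float, float, float] = (390 / 854, 447 / 854, 17 / 854)
    hb_thresholds: tuple[float, float] = (115.0, 150.0)
    class_sep: float = 3.0
    categorical_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or any(c <= 0 for c in self.n_features_per_tier):
            raise ConfigurationError("counts must be positive")
        if self.latent_rank <= 0:
            raise ConfigurationError("latent_rank must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ConfigurationError("class_mix proportions must be nonnegative")
        lo, hi = self.hb_thresholds
        if not lo < hi:
            raise ConfigurationError("lower Hb threshold must be < upper")


_TIER_ORDER = (MissingnessTier.NO_MISSING, MissingnessTier.NOT_EASY,
               MissingnessTier.EASY)
_TIER_PREFIX = {MissingnessTier.NO_MISSING: "base",
                MissingnessTier.NOT_EASY: "lab",
                MissingnessTier.EASY: "late"}


def assign_labels(hb: Sequence[float] | np.ndarray,
                  thresholds: tuple[float, float] = (115.0, 150.0)) -> LabelVector:
    """Threshold haemoglobin (g/L) into classes.

    Values inside [low, high] (boundaries inclusive) are normal (0); below
    low is low (1); above high is high (2).
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ConfigurationError("thresholds must be ordered")
    hb = np.asarray(hb, dtype=float)
    if not np.isfinite(hb).all():
        raise ValueError("haemoglobin values must be finite")
    labels = np.zeros(hb.shape, dtype=int)
    labels[hb < lo] = 1
    labels[hb > hi] = 2
    return LabelVector(labels=labels, source_hb=hb)


def _class_latent_means(rank: int, sep: float) -> np.ndarray:
    """Class-conditional means in latent space: three vertices sep apart."""
    mu = np.zeros((3, rank))
    mu[1, 0] = sep
    if rank >= 2:
        mu[2, 1] = sep
    else:
        mu[2, 0] = 2.0 * sep
    return mu


def generate_cohort(config: GeneratorConfig) -> tuple[FeatureTable, LabelVector]:
    """Draw a complete cohort from the latent factor model.

    Per sample a class is drawn from ``class_mix``; the latent factor vector
    is a class-dependent mean plus standard normal noise; each feature is a
    linear combination of the factors plus ``noise_sd`` observation noise.
    Haemoglobin is drawn inside the class's threshold band, so labels are the
    deterministic image of the thresholds.  Categorical features are latent
    scores discretized into quantile bins.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    counts = config.n_features_per_tier
    p = sum(counts)
    r = config.latent_rank

    classes = rng.choice(3, size=n, p=np.asarray(config.class_mix))
    mu = _class_latent_means(r, config.class_sep)
    z = mu[classes] + rng.standard_normal((n, r))
    loadings = rng.standard_normal((p, r)) / math.sqrt(r)
    x = z @ loadings.T
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal((n, p))

    meta: list[FeatureMeta] = []
    col = 0
    for tier, cnt in zip(_TIER_ORDER, counts):
        n_cat = int(round(config.categorical_fraction * cnt))
        for j in range(cnt):
            kind = "categorical" if j < n_cat else "continuous"
            meta.append(FeatureMeta(f"{_TIER_PREFIX[tier]}_{j:02d}", tier, kind))
            if kind == "categorical":
                q = np.quantile(x[:, col], [1 / 3, 2 / 3])
                x[:, col] = np.digitize(x[:, col], q).astype(float)
            col += 1

    lo, hi = config.hb_thresholds
    hb = np.empty(n)
    is0, is1, is2 = classes == 0, classes == 1, classes == 2
    hb[is0] = rng.uniform(lo, hi, is0.sum())
    hb[is1] = lo - 0.5 - rng.uniform(0.0, 45.0, is1.sum())
    hb[is2] = hi + 0.5 + rng.uniform(0.0, 20.0, is2.sum())

    table = FeatureTable(x, np.zeros((n, p), dtype=bool), meta)
    labels = assign_labels(hb, config.hb_thresholds)
    assert np.array_equal(labels.labels, classes)
    return table, labels


def inject_missingness(table: FeatureTable, case_fraction: float,
                       seed: int = 0) -> tuple[FeatureTable, np.ndarray]:
    """Worst-case block deletion: for a random fraction of cases, mask every
    fillable-tier entry, leaving only basic/pre-operative information.

    Returns the masked table and the indices of the deleted cases.  Case
    count rounds to the nearest integer, with at least one case whenever the
    fraction is positive.
    """
    if not 0.0 <= case_fraction <= 1.0:
        raise ValueError("case_fraction must lie in [0, 1]")
    out = table.copy()
    if case_fraction == 0.0:
        return out, np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    n_cases = max(1, int(round(case_fraction * table.n_samples)))
    rows = rng.choice(table.n_samples, size=n_cases, replace=False)
    cols = out.fillable_columns
    out.mask[np.ix_(rows, cols)] = True
    return out, np.sort(rows)


def inject_tiered_missingness(table: FeatureTable,
                              rates: tuple[float, float, float],
                              seed: int = 0) -> FeatureTable:
    """Entrywise MCAR masking with a per-tier rate (NO_MISSING rate must be 0)."""
    if any(not 0.0 <= rate <= 1.0 for rate in rates):
        raise ValueError("rates must lie in [0, 1]")
    if rates[0] != 0.0:
        raise ValueError("the NO_MISSING tier rate must be 0")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for tier, rate in zip(_TIER_ORDER, rates):
        if rate == 0.0:
            continue
        cols = out.columns_of_tier(tier)
        hit = rng.random((out.n_samples, cols.size)) < rate
        out.mask[:, cols] |= hit
    return out
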