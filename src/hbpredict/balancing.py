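"""Adaptive synthetic oversampling (ADASYN) for imbalanced outcome classes.

ADASYN raises minority-class counts toward the majority by interpolating new
samples between existing minority points, allocating more synthetics to
points whose neighbourhoods are dominated by other classes (the hard-to-learn
border regions).  Implemented here directly: per minority class with m
members, G = (majority - m) * beta synthetics are apportioned across members
proportionally to the fraction of non-minority points among their k nearest
neighbours (largest-remainder rounding so quotas sum exactly to G), and each
synthetic is x + lambda * (x_neighbour - x) with lambda ~ U(0,1) and the
neighbour drawn among the k nearest same-class points.  Categorical features
are copied from the nearer parent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import FeatureTable, LabelVector
from .errors import ConfigurationError

__all__ = ["BalanceConfig", "BalancedSet", "adasyn", "class_distribution"]


@dataclass(frozen=True)
class BalanceConfig:
    """k for the density estimate, beta the target balance ratio in (0, 1],
    and which classes to oversample ("not_majority": every non-majority
    class; "minority": only the smallest class)."""

    k_neighbors: int = 5
    beta: float = 1.0
    seed: int = 0
    strategy: str = "not_majority"

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if not 0.0 < self.beta <= 1.0:
            raise ConfigurationError("beta must lie in (0, 1]")
        if self.strategy not in ("not_majority", "minority"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")


@dataclass
class BalancedSet:
    table: FeatureTable
    labels: LabelVector
    origin: np.ndarray  # per-row tag: "real" | "synthetic"
    counts_before: dict[int, int]
    counts_after: dict[int, int]


def class_distribution(labels: LabelVector | np.ndarray) -> dict:
    """Exact per-class counts and proportions."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty label vector")
    uniq, counts = np.unique(y, return_counts=True)
    total = int(y.size)
    return {
        "counts": {int(c): int(n) for c, n in zip(uniq, counts)},
        "proportions": {int(c): n / total for c, n in zip(uniq, counts)},
        "total": total,
    }


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing exactly to ``total``, proportional to weights."""
    if total == 0:
        return np.zeros(weights.size, dtype=int)
    s = weights.sum()
    w = np.full(weights.size, 1.0 / weights.size) if s == 0 else weights / s
    raw = w * total
    quota = np.floor(raw).astype(int)
    rem = total - quota.sum()
    if rem > 0:
        order = np.argsort(-(raw - quota), kind="stable")
        quota[order[:rem]] += 1
    return quota


def adasyn(table: FeatureTable, labels: LabelVector,
           config: BalanceConfig | None = None) -> BalancedSet:
    """Oversample minority classes by density-weighted interpolation.

    The input table must be complete (post-imputation).  Real rows are
    preserved unchanged and come first in the output; synthetic rows carry
    the "synthetic" origin tag.
    """
    config = config or BalanceConfig()
    if table.mask.any():
        raise ConfigurationError("table must be complete before balancing")
    y = labels.labels
    dist = class_distribution(labels)
    counts = dist["counts"]
    if len(counts) < 2:
        raise ValueError("at least two classes are required")

    rng = np.random.default_rng(config.seed)
    k = config.k_neighbors
    majority = max(sorted(counts), key=lambda c: counts[c])
    if config.strategy == "minority":
        smallest = min(sorted(counts), key=lambda c: counts[c])
        targets = [smallest]
    else:
        targets = [c for c in sorted(counts) if c != majority]

    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0)
    sd[sd == 0] = 1.0
    z = (table.values - mean) / sd
    cat = np.array([m.kind == "categorical" for m in table.meta])

    new_rows, new_labels = [], []
    for c in targets:
        m = counts[c]
        if m <= 1 or m < k + 1:
            warnings.warn(f"class {c}: too few members ({m}) for k={k}; skipped")
            continue
        g_total = int(round((counts[majority] - m) * config.beta))
        if g_total <= 0:
            continue
        idx_c = np.flatnonzero(y == c)
        # density weights: non-minority fraction among k NN in the full space
        d_all = cdist(z[idx_c], z)
        order = np.argsort(d_all, axis=1, kind="stable")
        r = np.empty(m)
        for i in range(m):
            neigh = order[i][order[i] != idx_c[i]][:k]
            r[i] = np.mean(y[neigh] != c)
        quotas = _largest_remainder(r, g_total)
        # same-class neighbour pools
        d_same = cdist(z[idx_c], z[idx_c])
        order_same = np.argsort(d_same, axis=1, kind="stable")
        for i in range(m):
            if quotas[i] == 0:
                continue
            pool = order_same[i][order_same[i] != i][:k]
            xi = table.values[idx_c[i]]
            for _ in range(quotas[i]):
                j = idx_c[pool[rng.integers(pool.size)]]
                lam = rng.random()
                row = xi + lam * (table.values[j] - xi)
                if cat.any():
                    row[cat] = (xi if lam <= 0.5 else table.values[j])[cat]
                new_rows.append(row)
                new_labels.append(c)

    if new_rows:
        values = np.vstack([table.values, np.array(new_rows)])
        y_out = np.concatenate([y, np.array(new_labels, dtype=int)])
    else:
        values = table.values.copy()
        y_out = y.copy()
    mask = np.zeros(values.shape, dtype=bool)
    out_table = FeatureTable(values, mask, list(table.meta))
    # synthetic rows have no source haemoglobin, so the trace is dropped
    out_labels = LabelVector(y_out, None)
    origin = np.array(["real"] * table.n_samples
                      + ["synthetic"] * len(new_rows))
    return BalancedSet(out_table, out_labels, origin, counts,
                       class_distribution(out_labels)["counts"])
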