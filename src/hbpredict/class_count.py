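"""Choosing the number of outcome classes ("best approximation method").

Clinical thresholds give *actual* partitions of the cohort (2 = normal vs
abnormal; 3 = low/normal/high at 115/150 g/L; 4 = additionally splitting low
at a severity threshold).  K-means on the feature table, ignoring clinical
meaning, gives *ideal* clusterings.  The class count is chosen by combining
the classic diagnostics of the ideal clustering (SSE elbow, mean silhouette)
with the information-theoretic similarity (NMI, homogeneity, completeness,
V-measure) between each candidate's actual partition and the ideal
clustering with the matching K — the candidate whose clinically defined
partition best approximates an unsupervised structure wins.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import (completeness_score, homogeneity_score,
                             normalized_mutual_info_score, silhouette_score,
                             v_measure_score)

from .cohort import FeatureTable, LabelVector, assign_labels
from .errors import ConfigurationError

__all__ = [
    "ClusteringDiagnostics", "PartitionSimilarity", "ClassCountDecision",
    "ideal_clustering", "elbow_k", "silhouette_k", "actual_partition",
    "partition_similarity", "best_approximation", "DEFAULT_SCHEMES",
]

#: clinical threshold schemes (g/L) per candidate class count; the 2- and
#: 4-class variants are conventions (merge to normal/abnormal; split the low
#: class at a severe-anaemia threshold of 80 g/L)
DEFAULT_SCHEMES = {
    2: {"thresholds": (115.0, 150.0)},
    3: {"thresholds": (115.0, 150.0)},
    4: {"thresholds": (115.0, 150.0), "severity": 80.0},
}


@dataclass
class ClusteringDiagnostics:
    """Per-K records of the unsupervised (ideal) clustering."""

    records: list[dict] = field(default_factory=list)

    def ks(self) -> list[int]:
        return [r["k"] for r in self.records]

    def sse(self) -> np.ndarray:
        return np.array([r["sse"] for r in self.records])

    def silhouettes(self) -> np.ndarray:
        return np.array([r["silhouette"] for r in self.records])

    def assignment(self, k: int) -> np.ndarray:
        for r in self.records:
            if r["k"] == k:
                return r["assignment"]
        raise KeyError(f"no clustering recorded for K={k}")


@dataclass(frozen=True)
class PartitionSimilarity:
    n_classes: int
    nmi: float
    homogeneity: float
    completeness: float
    v_measure: float


@dataclass
class ClassCountDecision:
    chosen_k: int
    elbow_k: int
    silhouette_k: int
    similarities: list[PartitionSimilarity]
    rationale: str


def ideal_clustering(table, k_range, seed: int = 0,
                     n_init: int = 10) -> ClusteringDiagnostics:
    """K-means over z-scored features for each K, with best-of-restarts.

    For K > min(k_range) an extra warm-started candidate (previous centres
    plus the worst-fit point) is evaluated, which guarantees the SSE curve is
    non-increasing in K.
    """
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table)
    n = x.shape[0]
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ConfigurationError("k_range must lie within [2, n_samples - 1]")
    mean, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd

    diag = ClusteringDiagnostics()
    prev_centers = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
        best = km
        if prev_centers is not None and prev_centers.shape[0] == k - 1:
            d = np.linalg.norm(z - prev_centers[
                np.argmin(np.linalg.norm(
                    z[:, None, :] - prev_centers[None], axis=2), axis=1)],
                axis=1)
            init = np.vstack([prev_centers, z[np.argmax(d)]])
            km_warm = KMeans(n_clusters=k, init=init, n_init=1,
                             random_state=seed).fit(z)
            if km_warm.inertia_ < best.inertia_:
                best = km_warm
        prev_centers = best.cluster_centers_
        sil = float(silhouette_score(z, best.labels_)) if k < n else 0.0
        diag.records.append({"k": k, "sse": float(best.inertia_),
                             "silhouette": sil,
                             "assignment": best.labels_.copy()})
    return diag


def elbow_k(diagnostics: ClusteringDiagnostics) -> int:
    """K at the sharpest turn of the SSE curve.

    The turn is the maximum discrete second difference
    SSE(K-1) - 2 SSE(K) + SSE(K+1); ties go to the smaller K.  A flat or
    linear curve has no curvature, so the smallest K is returned with a
    warning.
    """
    ks = diagnostics.ks()
    if len(ks) < 3:
        raise ConfigurationError("elbow detection needs at least 3 K values")
    sse = diagnostics.sse()
    second = sse[:-2] - 2 * sse[1:-1] + sse[2:]
    scale = max(abs(sse[0]), 1.0)
    if second.max() <= 1e-9 * scale:
        warnings.warn("SSE curve has no detectable elbow; returning smallest K")
        return ks[0]
    return ks[1 + int(np.argmax(second))]


def silhouette_k(diagnostics: ClusteringDiagnostics) -> int:
    """K maximizing the mean silhouette; ties go to the smaller K."""
    ks = diagnostics.ks()
    if len(ks) < 2:
        raise ConfigurationError("need at least 2 candidate K values")
    return ks[int(np.argmax(diagnostics.silhouettes()))]


def actual_partition(hb, n_classes: int, schemes: dict | None = None) -> np.ndarray:
    """Clinically defined partition of the cohort from haemoglobin values.

    2 classes: normal (0) vs abnormal (1).  3 classes: normal/low/high at
    the thresholds.  4 classes: the low class is split at a severity
    threshold (code 3 below it).
    """
    schemes = schemes or DEFAULT_SCHEMES
    if n_classes not in schemes:
        raise ConfigurationError(f"no scheme defined for {n_classes} classes")
    if isinstance(hb, LabelVector):
        if hb.source_hb is None:
            raise ConfigurationError("label vector carries no haemoglobin trace")
        hb = hb.source_hb
    hb = np.asarray(hb, dtype=float)
    scheme = schemes[n_classes]
    base = assign_labels(hb, scheme["thresholds"]).labels
    if n_classes == 2:
        return (base != 0).astype(int)
    if n_classes == 3:
        return base
    out = base.copy()
    out[(base == 1) & (hb < scheme["severity"])] = 3
    return out


def partition_similarity(ideal: np.ndarray, actual: np.ndarray) -> PartitionSimilarity:
    """Information-theoretic agreement between two partitions.

    Homogeneity and completeness take the clinically defined (actual)
    partition as the reference; the V-measure is their harmonic mean, which
    equals arithmetically normalized mutual information.
    """
    ideal = np.asarray(ideal)
    actual = np.asarray(actual)
    if ideal.shape != actual.shape:
        raise ValueError("partition length mismatch")
    return PartitionSimilarity(
        n_classes=int(np.unique(actual).size),
        nmi=float(normalized_mutual_info_score(actual, ideal)),
        homogeneity=float(homogeneity_score(actual, ideal)),
        completeness=float(completeness_score(actual, ideal)),
        v_measure=float(v_measure_score(actual, ideal)),
    )


def best_approximation(table, hb, candidates=(2, 3, 4), seed: int = 0,
                       schemes: dict | None = None,
                       diagnostics: ClusteringDiagnostics | None = None
                       ) -> ClassCountDecision:
    """Pick the class count whose clinical partition best matches the
    unsupervised clustering with the same K (maximum V-measure).

    Ties prefer the candidate agreeing with the SSE elbow, then the smaller
    K.  The elbow/silhouette diagnostics are computed over a K range that
    extends one past the largest candidate so the elbow is interior.
    """
    candidates = sorted(int(c) for c in candidates)
    if diagnostics is None:
        k_range = range(2, max(candidates) + 2)
        diagnostics = ideal_clustering(table, k_range, seed=seed)
    e_k = elbow_k(diagnostics)
    s_k = silhouette_k(diagnostics)

    sims = []
    for k in candidates:
        actual = actual_partition(hb, k, schemes)
        ideal = diagnostics.assignment(k)
        sim = partition_similarity(ideal, actual)
        sims.append(dataclasses.replace(sim, n_classes=k))
    v = np.array([s.v_measure for s in sims])
    best_v = v.max()
    tied = [candidates[i] for i in np.flatnonzero(np.isclose(v, best_v))]
    if len(tied) == 1:
        chosen = tied[0]
    elif e_k in tied:
        chosen = e_k
    else:
        chosen = min(tied)
    rationale = (
        f"V-measure by candidate: "
        + ", ".join(f"K={s.n_classes}: {s.v_measure:.4f}" for s in sims)
        + f"; elbow K={e_k}, silhouette K={s_k}; chosen K={chosen}.")
    return ClassCountDecision(chosen, e_k, s_k, sims, rationale)
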