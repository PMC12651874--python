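"""K-means, DBSCAN, internal validity indices and their bootstrap.

All primitives are implemented from their textbook definitions:

* K-means: best-of-``n_init`` Lloyd iterations from k-means++ seeds,
  minimizing the within-cluster sum of squares
  WCSS = sum_j sum_{x in C_j} ||x - mu_j||^2.
* Elbow curve: WCSS per k, with an advisory knee at the maximum discrete
  second difference (elbows in practice are read off the plot).
* Validity indices: mean silhouette (singleton clusters score 0 by
  convention), Davies-Bouldin, Calinski-Harabasz.
* Out-of-bag bootstrap: per replicate, K-means is fitted on an in-bag
  resample, out-of-bag points are assigned to the nearest centroid, and
  the indices are computed on the out-of-bag points only — an "unseen
  data" estimate with percentile confidence intervals.
* DBSCAN: density-reachability clustering with the classic core-point
  expansion; noise is labelled -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KMeansResult", "IndexReport", "ClusterStats", "ElbowResult",
    "kmeans", "elbow_curve", "internal_indices", "bootstrap_indices",
    "dbscan", "cluster_descriptives",
    "silhouette_mean", "davies_bouldin", "calinski_harabasz",
]


@dataclass
class KMeansResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    n_init: int
    seed: int
    n_iter: int
    reseeded: int = 0  # empty-cluster repairs in the winning run


@dataclass
class IndexReport:
    silhouette: float
    davies_bouldin: float
    calinski_harabasz: float
    silhouette_ci: tuple[float, float] | None = None
    davies_bouldin_ci: tuple[float, float] | None = None
    calinski_harabasz_ci: tuple[float, float] | None = None
    n_replicates: int = 0
    n_skipped: int = 0
    replicates: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ClusterStats:
    """Per-cluster descriptives in the shape of the summary report tables."""

    cluster_ids: list[int]
    means: list[np.ndarray]
    variances: list[np.ndarray]
    sds: list[np.ndarray]
    sizes: list[int]


@dataclass
class ElbowResult:
    k_values: list[int]
    wcss: list[float]
    knee: int | None


def _sq_dists_to(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """n x k matrix of squared Euclidean distances to centroids."""
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(C * C, axis=1)[None, :]
        - 2.0 * X @ C.T
    )
    return np.maximum(d2, 0.0)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = _sq_dists_to(X, centroids[:1]).ravel()
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
        else:
            centroids[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _sq_dists_to(X, centroids[j:j + 1]).ravel())
    return centroids


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int = 300
           ) -> tuple[np.ndarray, np.ndarray, float, int, int]:
    k = len(centroids)
    labels = np.full(len(X), -1)
    reseeded = 0
    for it in range(max_iter):
        d2 = _sq_dists_to(X, centroids)
        new_labels = np.argmin(d2, axis=1)
        for j in range(k):
            if not np.any(new_labels == j):
                # empty cluster: reseed from the farthest point
                far = int(np.argmax(np.min(d2, axis=1)))
                centroids[j] = X[far]
                new_labels[far] = j
                reseeded += 1
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = X[labels == j].mean(axis=0)
    d2 = _sq_dists_to(X, centroids)
    labels = np.argmin(d2, axis=1)
    wcss = float(d2[np.arange(len(X)), labels].sum())
    return labels, centroids, wcss, it + 1, reseeded


def kmeans(X: np.ndarray, k: int, n_init: int = 10, seed: int = 0) -> KMeansResult:
    """Best-of-``n_init`` Lloyd runs from k-means++ initializations."""
    X = np.asarray(X, float)
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        init = _kmeanspp_init(X, k, rng)
        labels, centroids, wcss, n_iter, reseeded = _lloyd(X, init.copy())
        if best is None or wcss < best[2]:
            best = (labels, centroids, wcss, n_iter, reseeded)
    labels, centroids, wcss, n_iter, reseeded = best
    return KMeansResult(k=k, labels=labels, centroids=centroids, wcss=wcss,
                        n_init=n_init, seed=seed, n_iter=n_iter, reseeded=reseeded)


def elbow_curve(X: np.ndarray, k_range=range(1, 9), n_init: int = 10,
                seed: int = 0) -> ElbowResult:
    """WCSS versus k with an advisory knee (max second difference)."""
    X = np.asarray(X, float)
    ks = sorted(k_range)
    if ks[0] < 1 or ks[-1] > len(X):
        raise ValueError(f"k_range must lie within [1, {len(X)}]")
    wcss = [kmeans(X, k, n_init=n_init, seed=seed).wcss for k in ks]
    knee = None
    if len(ks) >= 3:
        second = np.diff(wcss, 2)
        knee = ks[int(np.argmax(second)) + 1]
    return ElbowResult(k_values=ks, wcss=wcss, knee=knee)


# ---------------------------------------------------------------------------
# Validity indices (textbook definitions)

def _check_labels(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("indices undefined for a single cluster")
    return [np.nonzero(labels == c)[0] for c in ids]


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b); singletons score 0."""
    members = _check_labels(X, labels)
    # direct differencing: avoids the cancellation error of the
    # dot-product expansion (these instances are small)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1))
    s = np.zeros(len(X))
    for ci, idx in enumerate(members):
        for i in idx:
            if len(idx) == 1:
                s[i] = 0.0
                continue
            a = d[i, idx].sum() / (len(idx) - 1)
            b = min(
                d[i, other].mean()
                for cj, other in enumerate(members) if cj != ci
            )
            s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """DB = mean over clusters of max_j (s_i + s_j) / d(c_i, c_j)."""
    members = _check_labels(X, labels)
    cents = np.array([X[idx].mean(axis=0) for idx in members])
    scatter = np.array([
        np.mean(np.sqrt(np.sum((X[idx] - cents[ci]) ** 2, axis=1)))
        for ci, idx in enumerate(members)
    ])
    k = len(members)
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            dij = float(np.linalg.norm(cents[i] - cents[j]))
            if dij == 0:
                return float("inf")
            worst = max(worst, (scatter[i] + scatter[j]) / dij)
        ratios[i] = worst
    return float(ratios.mean())


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """CH = [B / (k-1)] / [W / (n-k)] with B/W the between/within scatter."""
    members = _check_labels(X, labels)
    n, k = len(X), len(members)
    grand = X.mean(axis=0)
    between = sum(len(idx) * np.sum((X[idx].mean(axis=0) - grand) ** 2)
                  for idx in members)
    within = sum(np.sum((X[idx] - X[idx].mean(axis=0)) ** 2) for idx in members)
    if within == 0:
        return float("inf")
    return float((between / (k - 1)) / (within / (n - k)))


def internal_indices(X: np.ndarray, labels: np.ndarray) -> IndexReport:
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    return IndexReport(
        silhouette=silhouette_mean(X, labels),
        davies_bouldin=davies_bouldin(X, labels),
        calinski_harabasz=calinski_harabasz(X, labels),
    )


def bootstrap_indices(X: np.ndarray, k: int, B: int = 200, seed: int = 0,
                      n_init: int = 10) -> IndexReport:
    """Out-of-bag bootstrap of the validity indices under refitted K-means.

    Replicates whose out-of-bag set is smaller than k+1, or whose
    out-of-bag assignment collapses to a single cluster, are skipped and
    counted. The point estimates are the full-data indices.
    """
    X = np.asarray(X, float)
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(X)
    rng = np.random.default_rng(seed)
    full = kmeans(X, k, n_init=n_init, seed=seed)
    report = internal_indices(X, full.labels)
    sil, db, ch = [], [], []
    skipped = 0
    for b in range(B):
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if len(oob) < k + 1:
            skipped += 1
            continue
        fit = kmeans(X[in_bag], k, n_init=n_init,
                     seed=int(rng.integers(2**31)))
        oob_labels = np.argmin(_sq_dists_to(X[oob], fit.centroids), axis=1)
        if len(np.unique(oob_labels)) < 2:
            skipped += 1
            continue
        sil.append(silhouette_mean(X[oob], oob_labels))
        db.append(davies_bouldin(X[oob], oob_labels))
        ch.append(calinski_harabasz(X[oob], oob_labels))
    if not sil:
        raise ValueError("all bootstrap replicates were skipped")

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    report.silhouette_ci = ci(sil)
    report.davies_bouldin_ci = ci(db)
    report.calinski_harabasz_ci = ci(ch)
    report.n_replicates = len(sil)
    report.n_skipped = skipped
    report.replicates = {
        "silhouette": np.array(sil),
        "davies_bouldin": np.array(db),
        "calinski_harabasz": np.array(ch),
    }
    return report


# ---------------------------------------------------------------------------
# DBSCAN

def dbscan(X: np.ndarray, eps: float = 0.687, min_samples: int = 2) -> np.ndarray:
    """Density-reachability clustering; returns labels with noise = -1."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    X = np.asarray(X, float)
    n = len(X)
    d = np.sqrt(_sq_dists_to(X, X))
    neighbors = [np.nonzero(d[i] <= eps)[0] for i in range(n)]  # includes self
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        # expand a new cluster from this core point
        labels[i] = cluster
        frontier = list(neighbors[i])
        while frontier:
            j = frontier.pop()
            if labels[j] == -1:
                labels[j] = cluster
                if core[j]:
                    frontier.extend(neighbors[j])
        cluster += 1
    return labels


def cluster_descriptives(Y: np.ndarray, labels: np.ndarray) -> ClusterStats:
    """Per-cluster per-dimension mean, sample variance (n-1), SD and size.

    Singleton clusters report zero variance (flagged by their size 1).
    """
    Y = np.asarray(Y, float)
    labels = np.asarray(labels)
    ids = [int(c) for c in np.unique(labels)]
    means, variances, sds, sizes = [], [], [], []
    for c in ids:
        idx = labels == c
        if not np.any(idx):
            raise ValueError(f"empty cluster {c}")
        pts = Y[idx]
        means.append(pts.mean(axis=0))
        var = pts.var(axis=0, ddof=1) if len(pts) > 1 else np.zeros(Y.shape[1])
        variances.append(var)
        sds.append(np.sqrt(var))
        sizes.append(int(idx.sum()))
    return ClusterStats(cluster_ids=ids, means=means, variances=variances,
                        sds=sds, sizes=sizes)
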