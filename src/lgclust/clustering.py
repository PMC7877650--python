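"""Validated unsupervised-learning suite for growth-curve feature spaces.

The workflow mirrors standard clustering methodology: first test whether the
data are clusterable at all (Hopkins statistic), then choose the number of
clusters by majority vote across several validity indices, then cluster with
one or more algorithms — k-means as the benchmark, PAM/CLARA k-medoids whose
centres are actual data points, hierarchical clustering for dendrogram
inspection, and a SOM whose codebook is clustered and mapped back through
best-matching units.  Labels are arbitrary: agreement between methods is
always measured with the adjusted Rand index, never raw label equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .lgc import FeatureMatrix
from .som import SOMModel, som_train

__all__ = [
    "ClusterabilityReport",
    "KVoteReport",
    "ClusterAssignment",
    "LinkageResult",
    "hopkins",
    "vote_k",
    "kmeans",
    "pam",
    "clara",
    "hierarchical",
    "som_cluster",
]


def _X(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    X = np.asarray(features, dtype=float)
    return X[:, None] if X.ndim == 1 else X


# ---------------------------------------------------------------------------
# Clusterability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterabilityReport:
    """Hopkins statistic: ~0.5 for spatially random features, -> 1 for
    clustered ones.  Verdict thresholds: > 0.7 clusterable, <= 0.6 uniform,
    in between ambiguous."""

    hopkins: float
    n_sampled: int
    verdict: str
    seed: int


def hopkins(features, sample: int | None = None, seed: int = 0) -> ClusterabilityReport:
    """Hopkins clustering-tendency statistic H = sum(u) / (sum(u) + sum(w)).

    ``u``: nearest-data distances from uniform reference points drawn in the
    per-feature bounding box; ``w``: nearest-*other*-data distances from a
    random sample of the data itself.
    """
    X = _X(features)
    n = X.shape[0]
    if sample is None:
        sample = min(200, n // 2)
    if n < 2 * sample or sample < 1:
        raise ValueError("need n >= 2*sample and sample >= 1")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi == lo):
        raise ValueError("degenerate feature bounding box")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, sample, replace=False)
    tree = cKDTree(X)
    w = tree.query(X[idx], k=2)[0][:, 1]          # skip the point itself
    U = rng.uniform(lo, hi, size=(sample, X.shape[1]))
    u = tree.query(U, k=1)[0]
    H = float(u.sum() / (u.sum() + w.sum()))
    verdict = "clusterable" if H > 0.7 else ("uniform" if H <= 0.6 else "ambiguous")
    return ClusterabilityReport(H, sample, verdict, seed)


# ---------------------------------------------------------------------------
# Assignments and partitional methods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterAssignment:
    """Point labels in [0, k) plus cluster centres (medoids are data rows)."""

    labels: np.ndarray
    k: int
    centers: np.ndarray
    method: str
    seed: int | None = None
    medoid_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        labs = np.asarray(self.labels)
        if labs.min() < 0 or labs.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")
        if np.unique(labs).size != self.k:
            raise ValueError("every cluster must be non-empty")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def kmeans(features, k: int, seed: int = 0) -> ClusterAssignment:
    """k-means with k-means++ initialisation and 10 restarts (best inertia)."""
    X = _X(features)
    if not 1 <= k < X.shape[0]:
        raise ValueError("need 1 <= k < n")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(X)
    return ClusterAssignment(km.labels_, k, km.cluster_centers_, "kmeans", seed)


def _pam_core(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """PAM on a precomputed distance matrix: BUILD then steepest-descent SWAP.

    Returns the medoid indices.  The total-dissimilarity objective never
    increases across SWAP iterations.
    """
    n = D.shape[0]
    # BUILD: start from the most central point, then greedily add the point
    # giving the largest decrease in total dissimilarity.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        d_near = np.minimum(d_near, D[j])
    medoids = np.asarray(medoids)
    # SWAP
    for _ in range(max_iter):
        Dm = D[medoids]                     # k x n
        order = np.argsort(Dm, axis=0)
        near = order[0]                      # index into medoids
        d1 = Dm[near, np.arange(n)]
        d2 = Dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        best_delta, best_m, best_h = -1e-12, -1, -1
        for mi in range(k):
            owned = near == mi
            # points owned by medoid mi reattach to min(second-nearest, new h)
            t_owned = (np.minimum(D[owned], d2[owned, None]) - d1[owned, None]).sum(axis=0) if owned.any() else 0.0
            # points owned elsewhere can only improve by moving to h
            t_other = np.minimum(D[~owned] - d1[~owned, None], 0.0).sum(axis=0) if (~owned).any() else 0.0
            T = t_owned + t_other
            T[medoids] = np.inf
            h = int(np.argmin(T))
            if T[h] < best_delta:
                best_delta, best_m, best_h = float(T[h]), mi, h
        if best_m < 0:
            break
        medoids[best_m] = best_h
    return medoids


def pam(features, k: int, seed: int = 0) -> ClusterAssignment:
    """Partitioning around medoids (BUILD + SWAP), Euclidean distance.

    Deterministic regardless of seed (kept for interface symmetry).  Suited
    to moderate n (the full distance matrix is materialised); use
    :func:`clara` for large patterns.
    """
    X = _X(features)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    if n > 10000:
        raise ValueError("PAM materialises an n^2 distance matrix; use clara() for n > 10000")
    D = squareform(pdist(X))
    medoids = _pam_core(D, k)
    labels = np.argmin(D[medoids], axis=0)
    return ClusterAssignment(labels, k, X[medoids], "pam", seed, medoid_indices=medoids)


def clara(
    features,
    k: int,
    n_samples: int = 5,
    sample_size: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """CLARA: k-medoids for large n via repeated PAM on subsamples.

    Each of ``n_samples`` draws (default size 40 + 2k, the classical
    convention) is clustered with PAM; after the first draw every subsample
    is forced to contain the incumbent best medoids.  The medoid set with
    the smallest total dissimilarity over *all* points wins, and every point
    is assigned to its nearest medoid.
    """
    X = _X(features)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    if sample_size is None:
        sample_size = 40 + 2 * k
    if sample_size < k + 1:
        raise ValueError("sample_size must be >= k + 1")
    if sample_size > n:
        warnings.warn(f"sample_size {sample_size} > n {n}; clamped to n")
        sample_size = n
    rng = np.random.default_rng(seed)
    best_cost, best_medoids = np.inf, None
    for s in range(n_samples):
        if best_medoids is None:
            sub = rng.choice(n, sample_size, replace=False)
        else:
            pool = np.setdiff1d(np.arange(n), best_medoids)
            fill = rng.choice(pool, sample_size - k, replace=False)
            sub = np.concatenate([best_medoids, fill])
        D = squareform(pdist(X[sub]))
        med_local = _pam_core(D, k)
        medoids = sub[med_local]
        cost = float(cdist(X, X[medoids]).min(axis=1).sum())
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
    d = cdist(X, X[best_medoids])
    labels = np.argmin(d, axis=1)
    # a medoid whose cluster is captured entirely by another medoid would be
    # empty; reattach each medoid to itself to guarantee non-emptiness
    labels[best_medoids] = np.arange(k)
    return ClusterAssignment(labels, k, X[best_medoids], "clara", seed, medoid_indices=best_medoids)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageResult:
    """Agglomerative merge table (SciPy encoding) with heatmap leaf order."""

    Z: np.ndarray
    leaf_order: np.ndarray
    method: str
    n: int

    def cut(self, k: int) -> np.ndarray:
        """Labels in [0, k) from cutting the dendrogram into k clusters."""
        return fcluster(self.Z, k, criterion="maxclust") - 1

    def assignment(self, features, k: int) -> ClusterAssignment:
        labels = self.cut(k)
        X = _X(features)
        centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        return ClusterAssignment(labels, k, centers, f"hierarchical-{self.method}")


def hierarchical(features, method: str = "average", max_n: int = 10000) -> LinkageResult:
    """Agglomerative clustering with Euclidean distance (average linkage
    default).  Refuses n above ``max_n``: draw a random subsample first, as
    is standard for dendrogram/heatmap inspection of large patterns."""
    X = _X(features)
    n = X.shape[0]
    if n > max_n:
        raise ValueError(
            f"hierarchical clustering on n={n} exceeds max_n={max_n}; "
            "subsample the features first"
        )
    Z = scipy_linkage(X, method=method, metric="euclidean")
    return LinkageResult(Z, leaves_list(Z), method, n)


# ---------------------------------------------------------------------------
# SOM-based clustering
# ---------------------------------------------------------------------------

def som_cluster(model: SOMModel, features, k: int, method: str = "kmeans", seed: int = 0) -> ClusterAssignment:
    """Cluster the SOM codebook and push labels to the data through BMUs."""
    if model.n_units < k:
        raise ValueError("SOM grid has fewer units than requested clusters")
    X = _X(features)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(model.codebook)
        unit_labels = km.labels_
    elif method == "hierarchical":
        unit_labels = hierarchical(model.codebook).cut(k)
    else:
        raise ValueError(f"unknown codebook clustering method {method!r}")
    labels = unit_labels[model.bmu(X)]
    # relabel to the clusters actually hit by data, so none is empty
    present = np.unique(labels)
    remap = -np.ones(k, dtype=int)
    remap[present] = np.arange(present.size)
    labels = remap[labels]
    centers = np.vstack([model.codebook[unit_labels == j].mean(axis=0) for j in present])
    return ClusterAssignment(labels, present.size, centers, f"som+{method}", seed)


# ---------------------------------------------------------------------------
# Number-of-clusters voting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KVoteReport:
    """Votes of the validity indices over a k range, with majority winner."""

    k_range: list
    index_votes: dict
    majority_k: int
    scores: dict = field(default_factory=dict)


def _within_ss(X, labels, k) -> float:
    w = 0.0
    for j in range(k):
        pts = X[labels == j]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def vote_k(
    features,
    k_range=range(2, 9),
    method: str = "kmeans",
    seed: int = 0,
    gap_B: int = 10,
    silhouette_max_n: int = 3000,
) -> KVoteReport:
    """Choose the number of clusters by majority vote of validity indices.

    A single clustering method (k-means by default; "pam"/"clara" accepted)
    is fixed and run for every k in ``k_range``; each implemented index —
    silhouette, Calinski-Harabasz, Davies-Bouldin, the gap statistic
    (uniform reference, Tibshirani one-standard-error rule) and the
    within-SS elbow (maximum second difference) — casts one vote.  Ties go
    to the smallest k.  An index that fails is skipped with a warning.
    """
    X = _X(features)
    n = X.shape[0]
    ks = [int(k) for k in k_range]
    if not ks or min(ks) < 2 or max(ks) >= n:
        raise ValueError("k_range must lie within [2, n-1]")
    rng = np.random.default_rng(seed)
    fit = {"kmeans": kmeans, "pam": pam, "clara": clara}[method]
    labels_by_k = {}
    for k in ks:
        try:
            labels_by_k[k] = fit(features, k, seed=seed).labels
        except Exception as exc:  # e.g. fewer distinct rows than clusters
            warnings.warn(f"{method} unfittable at k={k}: {exc}")
    ks = [k for k in ks if k in labels_by_k]
    if not ks:
        raise ValueError("no k in k_range could be fitted")

    sil_idx = (
        rng.choice(n, silhouette_max_n, replace=False) if n > silhouette_max_n else np.arange(n)
    )
    scores: dict[str, dict[int, float]] = {}
    votes: dict[str, int] = {}

    def _score(name, fn, pick):
        vals = {}
        for k in ks:
            try:
                vals[k] = float(fn(k))
            except Exception as exc:  # index undefined for this k
                warnings.warn(f"{name} failed at k={k}: {exc}")
        if vals:
            scores[name] = vals
            votes[name] = pick(vals)

    _score(
        "silhouette",
        lambda k: silhouette_score(X[sil_idx], labels_by_k[k][sil_idx]),
        lambda v: min(v, key=lambda k: (-v[k], k)),
    )
    _score(
        "calinski_harabasz",
        lambda k: calinski_harabasz_score(X, labels_by_k[k]),
        lambda v: min(v, key=lambda k: (-v[k], k)),
    )
    _score(
        "davies_bouldin",
        lambda k: davies_bouldin_score(X, labels_by_k[k]),
        lambda v: min(v, key=lambda k: (v[k], k)),
    )

    # gap statistic
    W = {k: _within_ss(X, labels_by_k[k], k) for k in ks}
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_wref = {k: [] for k in ks}
    for b in range(gap_B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in ks:
            km = KMeans(n_clusters=k, n_init=1, random_state=seed + 1000 + b).fit(ref)
            log_wref[k].append(np.log(km.inertia_))
    gap = {k: float(np.mean(log_wref[k]) - np.log(max(W[k], 1e-12))) for k in ks}
    s = {k: float(np.std(log_wref[k]) * np.sqrt(1 + 1 / gap_B)) for k in ks}
    gap_k = None
    for a, bk in zip(ks[:-1], ks[1:]):
        if gap[a] >= gap[bk] - s[bk]:
            gap_k = a
            break
    scores["gap"] = gap
    votes["gap"] = gap_k if gap_k is not None else min(gap, key=lambda k: (-gap[k], k))

    # within-SS elbow: maximum second difference needs interior points
    scores["elbow_wss"] = W
    if len(ks) >= 3:
        second = {ks[i]: W[ks[i - 1]] - 2 * W[ks[i]] + W[ks[i + 1]] for i in range(1, len(ks) - 1)}
        votes["elbow_wss"] = min(second, key=lambda k: (-second[k], k))

    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    majority = min(counts, key=lambda k: (-counts[k], k))
    return KVoteReport(ks, votes, majority, scores)
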