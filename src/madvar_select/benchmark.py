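"""Evaluation harness: clustering, cluster-validity indices and a random-forest OOB loop.

Feature filters are compared by how well the retained features support
sample structure.  Samples are clustered (Ward hierarchical clustering on
Euclidean distances, or PAM k-medoids) and the partitions scored with three
validity indices:

* connectivity — for each sample, each of its L nearest neighbours (ranked
  j = 1..L) contributes 1/j when assigned to a different cluster; summed over
  samples.  In [0, inf), lower is better.
* Dunn index — smallest between-cluster distance over largest within-cluster
  distance.  In [0, inf), higher is better.
* BHI (biological homogeneity index) — per cluster with >= 2 members, the
  proportion of within-cluster sample pairs sharing an annotation class,
  averaged over clusters.  In [0, 1], higher is better.

Supervised performance is summarized by out-of-bag error rates of a random
forest (default 100 trees) refitted across many seeds (default 32); the
forest is an off-the-shelf learner used purely as an evaluation instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier

from .containers import FeatureMatrix
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "ClusterEval",
    "OOBResult",
    "connectivity",
    "dunn_index",
    "bhi",
    "run_clustering",
    "evaluate_clustering",
    "oob_harness",
]


@dataclass(frozen=True)
class ClusterEval:
    """The three validity indices for one clustering of the samples."""

    connectivity: float
    dunn: float
    bhi: float
    method: str  # hierarchical_ward | pam
    k: int
    neighbor_count: int


@dataclass(frozen=True)
class OOBResult:
    """Out-of-bag error rates across random-forest seeds."""

    error_rates: np.ndarray
    n_seeds: int
    n_trees: int

    def __post_init__(self):
        if len(self.error_rates) != self.n_seeds:
            raise InvalidInputError("one error rate per seed is required")


def _sample_matrix(m: FeatureMatrix) -> np.ndarray:
    """Samples as rows, features as columns (the clustering/learning orientation)."""
    return m.values.T


def _check_labels(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise InvalidInputError(f"expected {n} labels, got shape {labels.shape}")
    return labels


def connectivity(m: FeatureMatrix, clusters, L: int = 10) -> float:
    """Handl-style connectivity of a sample partition; lower is better.

    Neighbours are ranked by Euclidean distance with ties broken by sample
    index (stable sort).
    """
    X = _sample_matrix(m)
    n = X.shape[0]
    clusters = _check_labels(clusters, n)
    if L < 1:
        raise InvalidParameterError("L must be >= 1")
    if L >= n:
        raise InvalidParameterError(f"L={L} must be smaller than n_samples={n}")
    dist = squareform(pdist(X))
    total = 0.0
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbors = [j for j in order if j != i][:L]
        for rank, j in enumerate(neighbors, start=1):
            if clusters[j] != clusters[i]:
                total += 1.0 / rank
    return total


def dunn_index(m: FeatureMatrix, clusters) -> float:
    """Min inter-cluster distance over max intra-cluster distance; higher is better.

    When every cluster is a singleton the max intra-cluster distance is zero
    and the index is +inf (flagged via a warning).
    """
    X = _sample_matrix(m)
    n = X.shape[0]
    clusters = _check_labels(clusters, n)
    uniq = np.unique(clusters)
    if uniq.size < 2:
        raise InvalidInputError("Dunn index needs at least 2 clusters")
    dist = squareform(pdist(X))
    same = clusters[:, None] == clusters[None, :]
    iu = np.triu_indices(n, k=1)
    inter = dist[iu][~same[iu]]
    intra = dist[iu][same[iu]]
    min_inter = float(inter.min())
    if intra.size == 0 or intra.max() == 0:
        warnings.warn("all clusters are singletons or zero-diameter; Dunn index is +inf",
                      stacklevel=2)
        return float("inf")
    return min_inter / float(intra.max())


def bhi(clusters, annotations) -> float:
    """Biological homogeneity index of a partition against annotation classes.

    Per cluster with >= 2 members, the proportion of within-cluster sample
    pairs whose annotation classes match; these per-cluster proportions are
    averaged over the qualifying clusters.
    """
    clusters = np.asarray(clusters)
    annotations = np.asarray(annotations)
    if clusters.shape != annotations.shape:
        raise InvalidInputError("clusters and annotations must have the same length")
    props = []
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if idx.size < 2:
            continue
        ann = annotations[idx]
        match = sum(ann[i] == ann[j] for i in range(idx.size) for j in range(i + 1, idx.size))
        n_pairs = idx.size * (idx.size - 1) // 2
        props.append(match / n_pairs)
    if not props:
        raise InvalidInputError("BHI undefined: every cluster is a singleton")
    return float(np.mean(props))


def _pam(X: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Classic PAM (BUILD + SWAP) k-medoids on Euclidean distances; deterministic."""
    n = X.shape[0]
    dist = squareform(pdist(X))
    # BUILD: first medoid minimizes total distance; then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - dist[:, c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP: steepest-descent swaps until no improvement
    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    assign = np.argmin(dist[:, medoids], axis=1)
    return assign


def run_clustering(m: FeatureMatrix, method: str = "hierarchical_ward", k: int = 2) -> np.ndarray:
    """Cluster the samples on their feature profiles; returns integer labels.

    ``hierarchical_ward`` uses Euclidean distances with Ward agglomeration
    and cuts the tree at k clusters; ``pam`` is the deterministic
    BUILD+SWAP k-medoids partition.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    X = _sample_matrix(m)
    n = X.shape[0]
    if k > n:
        raise InvalidParameterError(f"k={k} exceeds n_samples={n}")
    if method == "hierarchical_ward":
        Z = linkage(X, method="ward", metric="euclidean")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    if method == "pam":
        return _pam(X, k)
    raise InvalidParameterError(f"unknown clustering method {method!r}")


def evaluate_clustering(
    m: FeatureMatrix,
    annotations,
    method: str = "hierarchical_ward",
    k: int = 2,
    L: int = 10,
) -> ClusterEval:
    """Cluster the samples and score the partition with all three indices."""
    labels = run_clustering(m, method=method, k=k)
    return ClusterEval(
        connectivity=connectivity(m, labels, L=L),
        dunn=dunn_index(m, labels),
        bhi=bhi(labels, annotations),
        method=method,
        k=k,
        neighbor_count=L,
    )


def oob_harness(m: FeatureMatrix, labels, n_seeds: int = 32, n_trees: int = 100) -> OOBResult:
    """Out-of-bag error of a random forest across seeds.

    Samples are the learner's rows (the transpose of the feature-matrix
    orientation); ``labels`` are the per-sample classes.  One forest with
    ``n_trees`` trees is fitted per seed and its OOB error recorded.
    """
    X = _sample_matrix(m)
    y = _check_labels(labels, X.shape[0])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise InvalidInputError("OOB harness needs at least 2 classes")
    if counts.min() < 2:
        warnings.warn("a class has a single member; OOB estimate is unstable", stacklevel=2)
    rates = []
    for seed in range(n_seeds):
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, bootstrap=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-trees OOB coverage warnings
            rf.fit(X, y)
        rates.append(1.0 - rf.oob_score_)
    return OOBResult(error_rates=np.array(rates), n_seeds=n_seeds, n_trees=n_trees)
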