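"""Correlation-based clustering of nucleosome profiles.

Genes are compared by the Pearson cross-correlation of their full 1200-bp
profiles, so two genes are similar when their signals rise and fall together
at the same positions, regardless of amplitude scaling. Clustering minimises
the correlation distance d = 1 - r; the number of clusters is chosen by the
mean silhouette under the same distance, and a Kolmogorov-Smirnov subsampling
protocol checks that the resulting partition separates profiles better than
size-matched random partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric gene-by-gene Pearson matrix with unit diagonal."""

    values: np.ndarray
    gene_ids: list[str]
    excluded_gene_ids: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    distance_metric: str
    n_init: int
    seed: int
    inertia: float = np.nan


@dataclass
class SignificanceResult:
    mean_p: float
    n_random_clusterings: int
    subsample_size: int
    alpha: float

    @property
    def significant(self) -> bool:
        return self.mean_p < self.alpha


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each row and scale to unit norm; returns (Z, constant_mask).

    After this transform, 1 - r(x, y) = ||zx - zy||^2 / 2, which turns
    correlation-distance k-means into spherical k-means on Z.
    """
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    return centered / safe[:, None], constant


def pearson_matrix(profiles) -> CorrelationMatrix:
    """Pairwise Pearson cross-correlation over full profiles.

    Constant rows (zero variance, correlation undefined) are excluded with a
    warning; the matrix covers the remaining genes in input order.
    """
    X = profiles.values if hasattr(profiles, "values") else np.asarray(profiles, float)
    gene_ids = (
        list(profiles.gene_ids)
        if hasattr(profiles, "gene_ids")
        else [str(i) for i in range(X.shape[0])]
    )
    Z, constant = _standardize_rows(X)
    excluded = [g for g, c in zip(gene_ids, constant) if c]
    if excluded:
        logger.warning("pearson_matrix: excluded %d constant profiles: %s",
                       len(excluded), excluded[:10])
        Z = Z[~constant]
        gene_ids = [g for g, c in zip(gene_ids, constant) if not c]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(values=R, gene_ids=gene_ids, excluded_gene_ids=excluded)


def _kmeans_once(
    Z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, float]:
    n = Z.shape[0]
    centroids = Z[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        dist = 1.0 - Z @ centroids.T
        new_labels = dist.argmin(axis=1)
        for j in range(k):
            if not np.any(new_labels == j):  # reseed empty cluster at worst point
                new_labels[dist.min(axis=1).argmax()] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            member_mean = Z[labels == j].mean(axis=0)
            member_mean -= member_mean.mean()
            norm = np.linalg.norm(member_mean)
            if norm > 0:
                centroids[j] = member_mean / norm
    inertia = float((1.0 - (Z * centroids[labels]).sum(axis=1)).sum())
    return labels, inertia


def kmeans_correlation(
    profiles, k: int, n_init: int = 25, seed: int = 0, max_iter: int = 100
) -> ClusterResult:
    """k-means under correlation distance (Lloyd's algorithm on
    row-standardized profiles with re-standardized centroids); the best of
    ``n_init`` random initialisations by within-cluster distance is kept."""
    X = profiles.values if hasattr(profiles, "values") else np.asarray(profiles, float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    Z, constant = _standardize_rows(X)
    if constant.any():
        raise ValueError("constant profiles present; run pearson_matrix to identify them")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_init):
        labels, inertia = _kmeans_once(Z, k, rng, max_iter)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    return ClusterResult(
        labels=best_labels,
        k=k,
        silhouette_by_k={},
        distance_metric="correlation",
        n_init=n_init,
        seed=seed,
        inertia=best_inertia,
    )


def select_k_silhouette(
    profiles,
    k_range=range(2, 7),
    n_init: int = 25,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose k maximising the mean silhouette under the 1 - r distance."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must not be empty")
    corr = pearson_matrix(profiles)
    D = 1.0 - corr.values
    np.fill_diagonal(D, 0.0)
    silhouette_by_k: dict[int, float] = {}
    for k in k_range:
        result = kmeans_correlation(profiles, k=k, n_init=n_init, seed=seed)
        if len(np.unique(result.labels)) < 2:
            silhouette_by_k[k] = -1.0
            continue
        silhouette_by_k[k] = float(
            silhouette_score(D, result.labels, metric="precomputed")
        )
    best_k = max(silhouette_by_k, key=silhouette_by_k.get)
    return best_k, silhouette_by_k


def _two_cluster_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 clusters, found {uniq.size}")
    return labels == uniq[0], labels == uniq[1]


def inter_cluster_correlations(
    correlations: CorrelationMatrix | np.ndarray,
    labels: np.ndarray,
    absolute: bool = True,
) -> np.ndarray:
    """All pairwise Pearson values between the two clusters (|r| by default)."""
    R = correlations.values if isinstance(correlations, CorrelationMatrix) else np.asarray(correlations)
    m1, m2 = _two_cluster_masks(labels)
    if not (m1.any() and m2.any()):
        raise ValueError("both clusters must be non-empty")
    vals = R[np.ix_(m1, m2)].ravel()
    return np.abs(vals) if absolute else vals


def cluster_significance(
    correlations: CorrelationMatrix | np.ndarray,
    labels: np.ndarray,
    n_random: int = 500,
    subsample: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    absolute: bool = True,
) -> SignificanceResult:
    """KS-subsampling significance of a 2-cluster partition.

    For each of ``n_random`` size-preserving random relabelings, ``subsample``
    inter-cluster correlation values are drawn from the observed and the
    random partition (with replacement when fewer pairs exist) and compared by
    a one-sided two-sample KS test with the alternative that the observed
    inter-cluster correlations are stochastically lower. The reported p-value
    is the mean over all repetitions.
    """
    R = correlations.values if isinstance(correlations, CorrelationMatrix) else np.asarray(correlations)
    labels = np.asarray(labels)
    observed = inter_cluster_correlations(R, labels, absolute=absolute)
    if observed.size < 2:
        raise ValueError("need at least 2 cross-cluster pairs")
    rng = np.random.default_rng(seed)
    n = labels.size
    pvals = np.empty(n_random)
    for i in range(n_random):
        perm = rng.permutation(n)
        random_vals = inter_cluster_correlations(R, labels[perm], absolute=absolute)
        obs_sub = rng.choice(observed, size=subsample, replace=observed.size < subsample)
        rand_sub = rng.choice(random_vals, size=subsample, replace=random_vals.size < subsample)
        # alternative='greater': observed CDF lies above -> values stochastically lower
        pvals[i] = ks_2samp(obs_sub, rand_sub, alternative="greater").pvalue
    return SignificanceResult(
        mean_p=float(pvals.mean()),
        n_random_clusterings=n_random,
        subsample_size=subsample,
        alpha=alpha,
    )


def balance_clusters(
    correlations: CorrelationMatrix | np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Equalise the two cluster sizes (|n1 - n2| <= 1).

    The genes moved are exactly the members of the larger cluster with the
    highest mean Pearson correlation to all members of the smaller cluster
    (one-shot ranking; ties broken by gene order)."""
    R = correlations.values if isinstance(correlations, CorrelationMatrix) else np.asarray(correlations)
    labels = np.asarray(labels).copy()
    m1, m2 = _two_cluster_masks(labels)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if abs(n1 - n2) <= 1:
        return labels
    large, small = (m1, m2) if n1 > n2 else (m2, m1)
    n_move = (max(n1, n2) - min(n1, n2)) // 2
    large_idx = np.flatnonzero(large)
    mean_corr = R[np.ix_(large, small)].mean(axis=1)
    # stable sort descending by mean correlation; ties keep gene order
    order = np.argsort(-mean_corr, kind="stable")
    movers = large_idx[order[:n_move]]
    small_label = labels[np.flatnonzero(small)[0]]
    labels[movers] = small_label
    return labels


def ward_euclidean_clusters(
    profiles,
    scores: np.ndarray,
    outlier_threshold: float = 20.0,
    k: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """WARD agglomerative clustering under Euclidean distance (validation
    route). Genes with max(|score|) above ``outlier_threshold`` are removed
    first, since the unbounded Euclidean metric is outlier-sensitive.

    Returns ``(labels_for_kept_genes, kept_mask)``.
    """
    X = profiles.values if hasattr(profiles, "values") else np.asarray(profiles, float)
    scores = np.asarray(scores, dtype=float)
    kept = np.max(np.abs(scores), axis=1) <= outlier_threshold
    n_removed = int((~kept).sum())
    if n_removed:
        logger.warning("ward_euclidean_clusters: removed %d outlier genes", n_removed)
    if kept.sum() < k:
        raise ValueError("all (or nearly all) genes removed by the outlier filter")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(X[kept])
    return labels, kept
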