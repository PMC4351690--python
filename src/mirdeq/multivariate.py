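"""PCA sample projection and average-linkage hierarchical clustering.

Samples are observations and miRNAs features. PCA mean-centers features
without variance scaling; the sign of each component is fixed so that its
largest-magnitude loading is positive. Clustering uses UPGMA (average
linkage) on either Pearson-correlation distance (1 - r, the default) or
Euclidean distance, with a two-cluster purity check against known group
labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from mirdeq.counts_io import SampleTable
from mirdeq.normalization import NormalizedMatrix


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x features


@dataclass
class Dendrogram:
    """UPGMA merge tree over samples.

    ``merges`` is a scipy-style linkage matrix: each row
    ``(node_a, node_b, height, size)`` merges two nodes (leaves are
    0..n-1, internal nodes n, n+1, ... in merge order).
    """

    leaf_ids: list[str]
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValueError("merge list inconsistent with leaf count")
        heights = self.merges[:, 2]
        if len(heights) > 1 and np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.leaf_ids[i] for i in order]

    def to_dict(self) -> dict:
        return {"leaf_ids": self.leaf_ids, "merges": self.merges.tolist()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def pca_scores(matrix: NormalizedMatrix, n_components: int) -> PCAResult:
    """Project samples onto principal components of the miRNA profiles.

    Features (miRNAs) are mean-centered, not variance-scaled. Components are
    ordered by decreasing explained variance; explained-variance fractions
    are 0 for a matrix with no variance at all.
    """
    # samples x features
    x = matrix.values.T.astype(float)
    n_samples, n_features = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    max_comp = min(n_samples, n_features)
    if n_components > max_comp or n_components < 1:
        raise ValueError(
            f"n_components={n_components} outside [1, {max_comp}]"
        )
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    variances = s**2 / (n_samples - 1)
    total = variances.sum()
    ratio = variances / total if total > 0 else np.zeros_like(variances)
    scores = scores[:, :n_components]
    vt = vt[:n_components].copy()
    ratio = ratio[:n_components]
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(n_components):
        i = int(np.argmax(np.abs(vt[k])))
        if vt[k, i] < 0:
            vt[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(list(matrix.sample_ids), scores, ratio, vt)


def _sample_distances(values: np.ndarray, sample_ids: list[str], metric: str):
    """Condensed distance vector between sample columns."""
    x = values.T.astype(float)
    if metric == "euclidean":
        return pdist(x, metric="euclidean")
    if metric == "pearson":
        sd = x.std(axis=1)
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"sample {sample_ids[j]!r} has a constant profile; "
                "Pearson distance is undefined"
            )
        return pdist(x, metric="correlation")  # 1 - Pearson r
    raise ValueError(f"unknown metric {metric!r}")


def hierarchical_cluster(
    matrix: NormalizedMatrix, metric: str = "pearson", standardize: bool = False
) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of samples.

    Distance is 1 - Pearson correlation between sample profiles by default;
    ``metric="euclidean"`` is available. ``standardize`` z-scores each miRNA
    across samples first (display convention, off by default).
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    values = matrix.values
    if standardize:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    dists = _sample_distances(values, list(matrix.sample_ids), metric)
    z = hierarchy.linkage(dists, method="average")
    return Dendrogram(list(matrix.sample_ids), z)


def cut_two(dendro: Dendrogram) -> np.ndarray:
    """Cluster labels (1/2) at the two-cluster cut of the dendrogram."""
    if len(dendro.leaf_ids) < 2:
        raise ValueError("need >= 2 leaves to cut into two clusters")
    return hierarchy.fcluster(dendro.merges, t=2, criterion="maxclust")


def two_group_purity(dendro: Dendrogram, samples: SampleTable) -> int:
    """Misclassified sample count at the 2-cluster cut.

    Each cluster is assigned the group label that minimizes mismatches
    (best cluster-to-group assignment); the return value is the total
    number of samples on the wrong side. Invariant under swapping the
    group names.
    """
    labels = cut_two(dendro)
    groups = np.array([samples.group_of(s) for s in dendro.leaf_ids])
    mis = 0
    for cluster in np.unique(labels):
        members = groups[labels == cluster]
        # majority assignment = unrestricted best mapping per cluster
        best = max((members == g).sum() for g in np.unique(groups))
        mis += len(members) - best
    return int(mis)
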