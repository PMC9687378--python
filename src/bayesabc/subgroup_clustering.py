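"""Subgroup discovery: Ward clustering of posterior vectors and the dendrogram cut.

Samples are clustered as vectors of Bayes posteriors over genes with
Euclidean distance and Ward minimum-variance linkage.  Because the
posteriors already live on [0, 1], no further normalization is applied
before clustering.  The number of subgroups is chosen where the fusion
levels of the dendrogram jump the most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "Dendrogram",
    "SubgroupPartition",
    "ward_cluster",
    "choose_cut",
    "contingency",
    "map_clusters_to_labels",
]


@dataclass(frozen=True)
class Dendrogram:
    """A Ward merge tree over samples (scipy linkage matrix plus ids)."""

    linkage: np.ndarray  # (n-1, 4): child a, child b, fusion height, size
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match the number of samples")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("fusion heights must be non-decreasing (Ward monotonicity)")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "size"]
        )


@dataclass(frozen=True)
class SubgroupPartition:
    """Sample -> cluster assignment for a chosen cluster count K."""

    assignments: dict[str, int]  # sample id -> 1..K
    k: int

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster]

    def group_members(self) -> dict[str, list[str]]:
        return {f"G{c}": self.members(c) for c in range(1, self.k + 1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": pd.Series(self.assignments, name="cluster")}
        ).rename_axis("sample_id")


def ward_cluster(posteriors: pd.DataFrame, sample_ids=None) -> Dendrogram:
    """Ward linkage over samples of a genes x samples posterior matrix.

    ``sample_ids`` restricts clustering to a subset (e.g., leukemia
    samples only, leaving normals for the differential comparisons).
    """
    if sample_ids is None:
        sample_ids = list(posteriors.columns)
    else:
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(posteriors.columns)
        if missing:
            raise KeyError(f"samples not in posterior matrix: {sorted(missing)}")
    if len(sample_ids) < 4:
        raise ValueError("need at least 4 samples to cluster")
    x = posteriors[sample_ids].to_numpy(dtype=float).T
    linkage = hierarchy.linkage(x, method="ward")
    return Dendrogram(linkage=linkage, sample_ids=tuple(sample_ids))


def choose_cut(dendrogram: Dendrogram, k_max: int = 10) -> SubgroupPartition:
    """Cut where successive top fusion heights jump the most.

    For each candidate K in 2..k_max the gap is the difference between
    the (K-1)-th and K-th highest fusion levels; the K with the largest
    gap wins, ties going to the smaller K.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    heights = np.sort(dendrogram.heights)
    n = len(dendrogram.sample_ids)
    k_hi = min(k_max, n - 1)
    gaps = {k: heights[n - k] - heights[n - k - 1] for k in range(2, k_hi + 1)}
    best_gap = max(gaps.values())
    if best_gap <= 1e-12:
        warnings.warn("all fusion heights are equal; defaulting to K=2")
        k = 2
    else:
        k = min(k for k, g in gaps.items() if g == best_gap)
    flat = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return SubgroupPartition(
        assignments={s: int(c) for s, c in zip(dendrogram.sample_ids, flat)}, k=k
    )


def contingency(partition: SubgroupPartition, annotations: pd.DataFrame) -> pd.DataFrame:
    """Cluster x label count table; unannotated samples count under "NA"."""
    samples = list(partition.assignments)
    labels = [
        str(annotations.at[s, "label"]) if s in annotations.index else "NA"
        for s in samples
    ]
    clusters = [f"G{partition.assignments[s]}" for s in samples]
    table = pd.crosstab(
        pd.Series(clusters, name="cluster"), pd.Series(labels, name="label")
    )
    return table.reindex(sorted(table.index), axis=0)


def map_clusters_to_labels(table: pd.DataFrame) -> dict[str, str]:
    """Majority annotation label per cluster (for scoring against truth)."""
    return {cluster: table.loc[cluster].idxmax() for cluster in table.index}
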