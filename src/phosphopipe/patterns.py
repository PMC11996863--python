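"""Row standardization, hierarchical clustering, variable-height cutting.

The heatmap-style pattern analysis: z-score each site across samples,
agglomerate with Euclidean distance (complete linkage by default), then
extract clusters by a recursive top-down variable-cut rule — a node splits
into its children only when both children are large enough and the merge
sits high in the tree, so tight subtrees of different heights become
separate clusters without one global cut height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format merge list plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: pd.Index
    linkage: str

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")
        if self.merges.shape[0] != len(self.leaves) - 1:
            raise ValueError("need exactly n-1 merges for n leaves")

    @property
    def root_height(self) -> float:
        return float(self.merges[-1, 2])

    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.merges).tolist()


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 (n-1 denominator).

    Constant rows cannot be standardized and are dropped with a warning.
    """
    vals = matrix.to_numpy(float)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant row(s) dropped before z-scoring", int(constant.sum()))
    keep = ~constant
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def hcluster(matrix: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of rows by Euclidean distance."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    d = pdist(matrix.to_numpy(float), metric="euclidean")
    merges = hierarchy.linkage(d, method=linkage)
    return Dendrogram(merges=merges, leaves=matrix.index, linkage=linkage)


def cut_variable_height(
    dendrogram: Dendrogram, min_size: int = 20, split_fraction: float = 0.8
) -> pd.Series:
    """Cluster labels by recursive variable-height splitting.

    Starting at the root, a node is split into its two children iff both
    children contain at least ``min_size`` leaves and the node's merge
    height exceeds ``split_fraction`` times the root height; unsplit
    subtrees become clusters.  Every leaf receives a label; cluster ids
    are integers ordered by the leftmost leaf of each cluster.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    n = len(dendrogram.leaves)
    merges = dendrogram.merges
    threshold = split_fraction * dendrogram.root_height

    # leaves under each internal node
    members: list[list[int]] = [[i] for i in range(n)]
    for left, right, _, _ in merges:
        members.append(members[int(left)] + members[int(right)])

    clusters: list[list[int]] = []

    def descend(node: int) -> None:
        if node < n:
            clusters.append([node])
            return
        row = merges[node - n]
        left, right, height = int(row[0]), int(row[1]), row[2]
        if (
            height > threshold
            and len(members[left]) >= min_size
            and len(members[right]) >= min_size
        ):
            descend(left)
            descend(right)
        else:
            clusters.append(members[node])

    descend(n + len(merges) - 1)
    clusters.sort(key=min)
    labels = np.empty(n, dtype=int)
    for cid, leaf_ids in enumerate(clusters, start=1):
        labels[leaf_ids] = cid
    return pd.Series(labels, index=dendrogram.leaves, name="cluster")
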