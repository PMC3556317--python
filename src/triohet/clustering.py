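"""Hierarchical clustering of samples on log2 expression.

Default distance is 1 - Pearson correlation across genes with average
linkage; uncentered correlation and Euclidean distance are offered as
alternatives.  Trees serialize to Newick with branch lengths equal to
merge-height differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["ClusterTree", "cluster_samples", "sample_distances"]

METRICS = ("correlation", "uncentered_correlation", "euclidean")
LINKAGES = ("average", "single", "complete")


@dataclass
class ClusterTree:
    """Agglomerative merge history over samples."""

    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels: list
    metric: str
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        root = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def sample_distances(x: pd.DataFrame, metric: str = "correlation") -> np.ndarray:
    """Pairwise sample distances (square matrix) over the gene axis."""
    vals = x.to_numpy(dtype=float).T  # samples x genes
    if metric == "euclidean":
        diff = vals[:, None, :] - vals[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    elif metric in ("correlation", "uncentered_correlation"):
        if metric == "correlation":
            centered = vals - vals.mean(axis=1, keepdims=True)
        else:
            centered = vals
        norms = np.sqrt((centered**2).sum(axis=1))
        flat = norms == 0
        if flat.any():
            bad = [x.columns[i] for i in np.flatnonzero(flat)]
            raise ValueError(f"constant sample(s) under {metric} metric: {bad}")
        corr = (centered @ centered.T) / np.outer(norms, norms)
        dist = 1.0 - np.clip(corr, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_samples(
    x: pd.DataFrame, metric: str = "correlation", linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of the columns (samples) of ``x``.

    ``x`` is a genes x samples matrix (log2 RPKM recommended) with no
    missing values.  Ties are broken deterministically by sample index
    (scipy's ordering).
    """
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if x.isna().to_numpy().any():
        raise ValueError("missing values in expression matrix")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    dist = sample_distances(x, metric=metric)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return ClusterTree(merges=z, labels=list(x.columns), metric=metric, linkage=linkage)
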