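"""Hierarchical clustering with Pearson-correlation distance and complete
linkage, plus Newick export of the resulting trees.

The distance between profiles i and j is d = 1 - r (Pearson), in [0, 2];
complete linkage merges the pair of clusters with the smallest maximum
pairwise member distance, which guarantees monotone (ultrametric) merge
heights. Trees are exported as Newick strings with merge heights encoded
as branch lengths so external tools can redraw the dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .errors import DataError


@dataclass
class ClusterTree:
    """A binary merge tree in scipy linkage form over named leaves."""

    linkage: np.ndarray  # (n-1) x 4 scipy linkage matrix
    leaf_ids: list[str]

    def __post_init__(self):
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise DataError("non-monotone merge heights (linkage inversion)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def leaf_order(self) -> list[str]:
        """Display order of leaves for heatmaps."""
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k flat clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {leaf: int(c) for leaf, c in zip(self.leaf_ids, labels)}

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.leaf_ids)
        buf = StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()


def pearson_distance(x: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between the rows of x."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DataError(f"zero-variance rows cannot be correlated: {bad.tolist()}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def complete_linkage(d: np.ndarray, leaf_ids: list[str] | None = None) -> ClusterTree:
    """Agglomerative complete-linkage clustering of a distance matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise DataError("distance matrix must have a zero diagonal")
    if leaf_ids is None:
        leaf_ids = [f"leaf{i}" for i in range(d.shape[0])]
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return ClusterTree(linkage=z, leaf_ids=list(leaf_ids))


def cluster_heatmap_order(
    x: pd.DataFrame, de: pd.DataFrame, level: str = "L1"
) -> tuple[ClusterTree, ClusterTree, pd.DataFrame]:
    """Cluster the significant probes (rows) and the arrays (columns).

    ``x`` is the log2 expression frame (probes x arrays); ``de`` the DE
    table whose ``level`` column selects the probes to display. Returns the
    row tree, the column tree and the matrix reordered to their leaf
    orders.
    """
    probes = de.index[de["level"] == level]
    probes = [p for p in probes if p in x.index]
    if len(probes) < 2:
        raise DataError(
            f"need >= 2 probes at level {level!r} to cluster, got {len(probes)}"
        )
    sub = x.loc[probes]
    row_tree = complete_linkage(pearson_distance(sub.to_numpy()), list(sub.index))
    col_tree = complete_linkage(
        pearson_distance(sub.to_numpy().T), list(sub.columns)
    )
    ordered = sub.loc[row_tree.leaf_order(), col_tree.leaf_order()]
    return row_tree, col_tree, ordered


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string back into a tree (round-trip helper)."""
    return TreeNode.read(StringIO(newick), format="newick")
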