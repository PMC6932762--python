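"""Hierarchical clustering of paired expression differences.

Each analyzed fragment becomes a vector of per-participant RPM
differences (Sugar - Healthy), centred and scaled to unit sample SD
(n-1 denominator).  Rows are clustered agglomeratively on Euclidean
distances; the dendrogram can be exported as Newick and cut into k
clusters to score how cleanly nuclear and mitochondrial fragments
separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .mapping import ExpressionTable

__all__ = [
    "DifferenceMatrix",
    "ClusterTree",
    "build_difference_matrix",
    "hierarchical_cluster",
    "cluster_purity",
]


@dataclass
class DifferenceMatrix:
    """Center-scaled per-participant difference vectors, one row per unit."""

    values: np.ndarray            # (n_units, n_participants)
    row_ids: list[str]
    participants: list[str]
    dropped_zero_variance: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length does not match matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=self.participants
        )


@dataclass
class ClusterTree:
    linkage: np.ndarray           # scipy linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cut(self, k: int) -> np.ndarray:
        if k > self.n_leaves:
            raise ValueError(f"cannot cut {self.n_leaves} leaves into {k} clusters")
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return recurse(tree, tree.dist) + ";"


def build_difference_matrix(
    table: ExpressionTable,
    unit_set: Sequence[str] | None = None,
    contrast: tuple[str, str] = ("Sugar", "Healthy"),
) -> DifferenceMatrix:
    """Per-unit vectors of per-participant RPM differences, z-scaled by row.

    Participants missing either timepoint are excluded.  Rows with zero
    variance across participants carry no relational information and are
    dropped (recorded in ``dropped_zero_variance``).
    """
    num, den = contrast
    participants = table.complete_participants((num, den))
    if not participants:
        raise ValueError("no participant has both contrast timepoints")
    cols_num = [table.sample_index(p, num) for p in participants]
    cols_den = [table.sample_index(p, den) for p in participants]
    ids = list(unit_set) if unit_set is not None else table.sequences
    index = {s: i for i, s in enumerate(table.sequences)}

    rows, kept, dropped = [], [], []
    for uid in ids:
        i = index[uid]
        diff = table.rpm[i, cols_num] - table.rpm[i, cols_den]
        sd = diff.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(uid)
            continue
        rows.append((diff - diff.mean()) / sd)
        kept.append(uid)
    values = np.array(rows).reshape(len(kept), len(participants))
    return DifferenceMatrix(values, kept, participants, dropped)


def hierarchical_cluster(
    matrix: DifferenceMatrix, linkage: str = "complete"
) -> ClusterTree:
    """Agglomerative clustering of rows on Euclidean distances.

    Complete linkage by default; single/average/ward accepted.  Needs at
    least two rows.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    dists = pdist(matrix.values, metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage)
    return ClusterTree(linkage=Z, leaf_ids=list(matrix.row_ids))


def cluster_purity(
    tree: ClusterTree, labels: Sequence[str], k: int = 2
) -> float:
    """Majority-label purity of a k-cut.

    Cut the dendrogram into k flat clusters; purity is the fraction of
    leaves whose cluster's majority label matches their own.  Singleton
    clusters are pure by definition.
    """
    if len(labels) != tree.n_leaves:
        raise ValueError("one label per leaf required")
    assign = tree.cut(k)
    labels = np.asarray(labels)
    correct = 0
    for c in np.unique(assign):
        members = labels[assign == c]
        values, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / tree.n_leaves
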