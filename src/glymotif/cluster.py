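"""Hierarchical clustering of lectin binding profiles.

Lectins are compared by the Pearson correlation of their processed Zs profiles
over glycans (distance d = 1 − r) and merged by average linkage (UPGMA).
Glycan-axis clustering with identical settings is provided for two-way
heatmaps. Input columns are ordered lexicographically before linkage so tied
merges resolve deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "pearson_distances",
    "average_linkage",
    "cluster_profiles",
    "heatmap_export",
]


@dataclass
class DistanceMatrix:
    """Symmetric 1 − Pearson-r distances with zero diagonal, 0 ≤ d ≤ 2."""

    ids: list[str]
    values: pd.DataFrame

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


@dataclass
class ClusterResult:
    ids: list[str]
    linkage: np.ndarray            # scipy linkage matrix
    leaf_order: list[str]

    def flat_clusters(self, k: int) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.ids, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.ids[node.id].replace(" ", "_")
            left, right = render(node.left), render(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return render(tree) + ";"


def pearson_distances(profiles: pd.DataFrame) -> DistanceMatrix:
    """d(i,j) = 1 − Pearson r between columns of ``profiles`` (observations ×
    profiles). Raises for any zero-variance profile, naming it."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    profiles = profiles.reindex(sorted(profiles.columns), axis=1)
    sd = profiles.std(ddof=0)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance profile(s): {list(dead.index)}")
    corr = np.corrcoef(profiles.to_numpy(), rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry
    ids = list(profiles.columns)
    return DistanceMatrix(ids=ids, values=pd.DataFrame(d, index=ids, columns=ids))


def average_linkage(dm: DistanceMatrix) -> ClusterResult:
    """UPGMA merge tree on the distance matrix; exports the heatmap leaf order."""
    Z = hierarchy.linkage(dm.condensed(), method="average")
    order = [dm.ids[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(ids=dm.ids, linkage=Z, leaf_order=order)


def cluster_profiles(processed: pd.DataFrame, axis: str = "lectins") -> ClusterResult:
    """Cluster lectin columns (default) or glycan rows of the processed matrix."""
    profiles = processed if axis == "lectins" else processed.T
    return average_linkage(pearson_distances(profiles))


def heatmap_export(
    processed: pd.DataFrame,
    lectin_result: ClusterResult,
    glycan_result: ClusterResult | None = None,
    threshold: float = 1.645,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matrix reordered by dendrogram leaves plus the binary bound layer
    (Zs > threshold), ready for external plotting."""
    rows = glycan_result.leaf_order if glycan_result else list(processed.index)
    ordered = processed.loc[rows, lectin_result.leaf_order]
    return ordered, (ordered > threshold).astype(int)
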