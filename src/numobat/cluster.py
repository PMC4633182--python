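"""Nest-centroid (NC) clustering.

The exploratory step of the workflow: nests are represented by their
per-trait mean vectors, each trait is z-scored across nests, and the
nests are clustered agglomeratively under both average linkage (UPGMA)
and Ward's minimum-variance criterion (Ward.D2 convention: Euclidean
input distances, squared inside the update).  Cutting both trees at the
same number of groups and matching the groups by maximum overlap gives
a classification hypothesis: nests on which the two linkages agree get
a cluster label, the rest become wild-cards for the confirmatory LDA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .core import TRAIT_NAMES, NestSample

__all__ = [
    "WILDCARD",
    "CentroidMatrix",
    "Dendrogram",
    "ClusterHypothesis",
    "centroid_matrix",
    "agglomerate",
    "congruence_hypothesis",
]

WILDCARD = "WILDCARD"


@dataclass
class CentroidMatrix:
    """Z-scored nest-mean trait matrix (rows: nests, columns: traits)."""

    nest_ids: list[str]
    traits: list[str]
    matrix: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def distances(self) -> np.ndarray:
        """Condensed Euclidean distance vector between nest rows."""
        return pdist(self.matrix, metric="euclidean")


@dataclass
class Dendrogram:
    """Merge tree over nests; scipy linkage encoding with leaf labels."""

    leaf_labels: list[str]
    linkage: np.ndarray  # (n-1, 4): idx-a, idx-b, height, size
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` groups; returns nest_id → group index (1..k)."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}], got {k}")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.leaf_labels, (int(g) for g in flat)))

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def build(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{length:.10g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return build(tree, tree.dist) + ";"

    def merge_table(self) -> list[dict]:
        rows = []
        for a, b, h, size in self.linkage:
            rows.append(
                {"cluster_a": int(a), "cluster_b": int(b),
                 "height": float(h), "size": int(size)}
            )
        return rows


@dataclass
class ClusterHypothesis:
    """Nest → cluster-label-or-WILDCARD map used to seed the LDA."""

    labels: dict[str, str]
    k: int

    @property
    def wildcards(self) -> list[str]:
        return [n for n, lab in self.labels.items() if lab == WILDCARD]


def centroid_matrix(
    nests: list[NestSample],
    traits: list[str] | None = None,
) -> CentroidMatrix:
    """Build the z-scored nest-centroid matrix.

    Each column is standardized to mean 0 and (population) sd 1 across
    nests; traits constant over all nests carry no signal and are
    dropped with a warning.
    """
    if len(nests) < 2:
        raise ValueError("need at least 2 nests")
    traits = list(traits) if traits is not None else list(TRAIT_NAMES)
    raw = np.array([[nest.trait_means[t] for t in traits] for nest in nests])
    sd = raw.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [t for t, k in zip(traits, keep) if not k]
    if dropped:
        warnings.warn(f"constant trait(s) dropped: {dropped}", stacklevel=2)
    z = (raw[:, keep] - raw[:, keep].mean(axis=0)) / sd[keep]
    return CentroidMatrix(
        nest_ids=[n.nest_id for n in nests],
        traits=[t for t, k in zip(traits, keep) if k],
        matrix=z,
        dropped=dropped,
    )


_LINKAGE_METHODS = {"UPGMA": "average", "WARD": "ward"}


def agglomerate(centroids: CentroidMatrix, linkage: str = "UPGMA") -> Dendrogram:
    """Agglomerative clustering of nest centroids.

    ``linkage`` is ``"UPGMA"`` (average linkage on Euclidean distances)
    or ``"WARD"`` (Ward.D2).  Merge heights are the linkage distances.
    """
    method = _LINKAGE_METHODS.get(linkage.upper())
    if method is None:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGE_METHODS)}")
    dist = centroids.distances()
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    Z = hierarchy.linkage(dist, method=method)
    return Dendrogram(
        leaf_labels=list(centroids.nest_ids), linkage=Z, method=linkage.upper()
    )


def congruence_hypothesis(
    dendro_upgma: Dendrogram,
    dendro_ward: Dendrogram,
    k: int,
) -> ClusterHypothesis:
    """Cross-linkage congruence at ``k`` groups.

    Groups of the two trees are matched by maximum overlap (optimal
    one-to-one assignment); a nest keeps its group label only when its
    UPGMA group and its Ward group are matched to each other, otherwise
    it becomes a wild-card.
    """
    if set(dendro_upgma.leaf_labels) != set(dendro_ward.leaf_labels):
        raise ValueError("dendrograms cover different nests")
    cut_u = dendro_upgma.cut(k)
    cut_w = dendro_ward.cut(k)
    groups_u = sorted(set(cut_u.values()))
    groups_w = sorted(set(cut_w.values()))
    overlap = np.zeros((len(groups_u), len(groups_w)), dtype=int)
    for nest in cut_u:
        overlap[groups_u.index(cut_u[nest]), groups_w.index(cut_w[nest])] += 1
    rows, cols = linear_sum_assignment(-overlap)
    matched = {
        (groups_u[r], groups_w[c]): f"cluster-{i + 1}"
        for i, (r, c) in enumerate(zip(rows, cols))
    }
    labels = {
        nest: matched.get((cut_u[nest], cut_w[nest]), WILDCARD)
        for nest in dendro_upgma.leaf_labels
    }
    return ClusterHypothesis(labels=labels, k=k)
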