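"""Cross-time-point set logic and hierarchical clustering.

:func:`venn3` computes the three-way overlap of per-time-point significant
probe sets (the basis of the study's Venn diagrams); the "common percentage"
is 100 x |triple intersection| / |union of the three sets| — the union
denominator is an inferred convention, so raw counts are always reported
alongside. :func:`hierarchical_cluster` groups samples or probes with
1 - Pearson or Euclidean distance and average/complete linkage, the
conventions of classic microarray clustering tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .study_io import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class VennResult:
    sizes: dict[str, int]                 # per-set sizes keyed by set name
    pairwise: dict[tuple[str, str], int]  # pairwise intersection sizes
    common: set[str]                      # triple intersection membership
    union_size: int

    @property
    def common_size(self) -> int:
        return len(self.common)

    @property
    def common_percentage(self) -> float:
        """100 x |A∩B∩C| / |A∪B∪C| (0 when all sets are empty)."""
        return 100.0 * len(self.common) / self.union_size if self.union_size else 0.0


def venn3(
    set_t0: set[str],
    set_t2: set[str],
    set_t48: set[str],
    names: tuple[str, str, str] = ("T0", "T2", "T48"),
) -> VennResult:
    """Exact three-set algebra; empty sets are allowed."""
    a, b, c = set(set_t0), set(set_t2), set(set_t48)
    na, nb, nc = names
    return VennResult(
        sizes={na: len(a), nb: len(b), nc: len(c)},
        pairwise={(na, nb): len(a & b), (na, nc): len(a & c), (nb, nc): len(b & c)},
        common=a & b & c,
        union_size=len(a | b | c),
    )


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray      # scipy linkage format (merge pairs + heights)
    labels: list[str]               # items, input order (after any drops)
    dropped: list[str] = field(default_factory=list)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (item order = ``labels``)."""
        from scipy.cluster.hierarchy import cophenet

        return cophenet(self.linkage_matrix)

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples or probes.

    ``distance`` is ``"correlation"`` (1 - Pearson) or ``"euclidean"``;
    ``linkage`` is ``"average"`` or ``"complete"`` (both monotone, so merge
    heights never decrease). Items with zero variance are dropped with a
    warning under the correlation distance. Ties in the merge order resolve
    deterministically for a fixed input order.
    """
    if axis not in ("samples", "probes"):
        raise ValueError("axis must be 'samples' or 'probes'")
    if distance not in ("correlation", "euclidean"):
        raise ValueError("distance must be 'correlation' or 'euclidean'")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")

    frame = matrix.values if axis == "probes" else matrix.values.T
    labels = [str(x) for x in frame.index]
    obs = frame.to_numpy(dtype=float)
    dropped: list[str] = []
    if distance == "correlation":
        keep = obs.std(axis=1) > 0
        if not keep.all():
            dropped = [lab for lab, k in zip(labels, keep) if not k]
            log.warning("dropping zero-variance item(s) under correlation distance: %s",
                        ", ".join(dropped))
            obs = obs[keep]
            labels = [lab for lab, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")

    condensed = pdist(obs, metric=distance)
    condensed = np.maximum(condensed, 0.0)  # guard tiny negative rounding
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage_matrix=z, labels=labels, dropped=dropped)
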