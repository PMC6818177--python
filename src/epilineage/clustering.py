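"""Z-score normalisation, hierarchical clustering of cell types, and
comparison of the recovered dendrogram with a reference lineage.

Cell types (matrix columns) are clustered agglomeratively on Euclidean
distance (complete linkage by default) after per-row Z-scoring. Topology is
compared through bipartitions (the leaf splits induced by internal edges)
and, for nested paths such as NSC -> GNP -> glia with neurons as the
outgroup, through the full set of merge clusters: the lineage-consistent
outcome on four neural cell types is first merge {NSC, GNP}, then glia
joining, neurons last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .core import SignalMatrix

logger = logging.getLogger(__name__)

TIE_TOL = 1e-9


def zscore_rows(matrix: SignalMatrix) -> SignalMatrix:
    """Per-row Z-score (population standard deviation, divisor n).

    Zero-variance rows carry no between-cell information and are dropped
    (logged); an all-constant matrix is an error.
    """
    if len(matrix.col_ids) < 2:
        raise ValueError("need >= 2 columns to Z-score")
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population (ddof=0)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all rows have zero variance; nothing to cluster")
    if n_dropped:
        logger.info("zscore_rows: dropped %d zero-variance rows", n_dropped)
    z = (values[keep] - mean[keep]) / sd[keep]
    row_ids = [r for r, k in zip(matrix.row_ids, keep.tolist()) if k]
    return SignalMatrix(row_ids, matrix.col_ids, z, units="zscore")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over cell-type leaves."""

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]]  # (cluster A, cluster B, height)

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    @property
    def cluster_sets(self) -> list[frozenset]:
        """Leaf set produced by each merge, in merge order."""
        return [a | b for a, b, _ in self.merges]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    @property
    def unresolved(self) -> bool:
        """All merge heights equal within tolerance: topology is tie-broken only."""
        h = self.heights
        return max(h) - min(h) <= TIE_TOL

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf splits, each canonicalised as {sideA, sideB}."""
        full = frozenset(self.leaves)
        out = set()
        for cluster in self.cluster_sets:
            if 2 <= len(cluster) <= len(self.leaves) - 2:
                out.add(frozenset({cluster, full - cluster}))
        return out

    def newick(self) -> str:
        node_repr: dict[frozenset, str] = {frozenset([l]): l for l in self.leaves}
        node_h: dict[frozenset, float] = {frozenset([l]): 0.0 for l in self.leaves}
        for a, b, h in self.merges:
            parts = []
            for side in sorted((a, b), key=lambda s: sorted(s)):
                bl = h - node_h[side]
                parts.append(f"{node_repr[side]}:{bl:g}")
            merged = a | b
            node_repr[merged] = "(" + ",".join(parts) + ")"
            node_h[merged] = h
        return node_repr[frozenset(self.leaves)] + ";"


def hcluster_cells(matrix: SignalMatrix, method: str = "complete") -> Dendrogram:
    """Cluster matrix columns (cell types) by Euclidean distance.

    Columns are processed in lexicographic label order so that ties in the
    distance matrix break deterministically.
    """
    if method not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {method!r}")
    if len(matrix.col_ids) < 3:
        raise ValueError("need >= 3 columns to cluster")
    order = sorted(range(len(matrix.col_ids)), key=lambda i: matrix.col_ids[i])
    labels = [matrix.col_ids[i] for i in order]
    X = matrix.values[:, order].T
    Z = linkage(X, method=method, metric="euclidean")
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    merges: list[tuple[frozenset, frozenset, float]] = []
    for row in Z:
        a, b = clusters[int(row[0])], clusters[int(row[1])]
        merges.append((a, b, float(row[2])))
        clusters.append(a | b)
    return Dendrogram(labels, merges)


def hcluster_genes(matrix: SignalMatrix, method: str = "complete") -> list[str]:
    """Leaf order of gene-axis clustering (display ordering for heatmaps)."""
    from scipy.cluster.hierarchy import leaves_list

    if len(matrix.row_ids) < 3:
        raise ValueError("need >= 3 rows to cluster")
    Z = linkage(matrix.values, method=method, metric="euclidean")
    return [matrix.row_ids[i] for i in leaves_list(Z)]


@dataclass
class TopologyComparison:
    """Inferred vs reference bipartitions, plus the nested merge-order check."""

    inferred_bipartitions: set[frozenset]
    reference_bipartitions: set[frozenset]
    bipartition_match: dict[frozenset, bool]
    exact_match: bool
    nested_order_match: bool
    unresolved: bool

    def summary(self) -> dict:
        def fmt(bp: frozenset) -> str:
            sides = sorted(["|".join(sorted(s)) for s in bp])
            return " vs ".join(sides)

        return {
            "exact_match": self.exact_match,
            "nested_order_match": self.nested_order_match,
            "unresolved": self.unresolved,
            "bipartitions": {fmt(bp): ok for bp, ok in self.bipartition_match.items()},
        }


def _reference_clusters(topology) -> list[frozenset]:
    """Internal-node leaf sets of a nested-tuple topology, e.g.
    ((("NSC","GNP"),"Glia"),"Neuron")."""
    clusters: list[frozenset] = []

    def walk(node) -> frozenset:
        if isinstance(node, str):
            return frozenset([node])
        parts = [walk(child) for child in node]
        merged = frozenset().union(*parts)
        clusters.append(merged)
        return merged

    walk(topology)
    return clusters


def compare_topology(dendrogram: Dendrogram, reference) -> TopologyComparison:
    """Compare an inferred dendrogram with a reference lineage.

    ``reference`` is a nested-tuple topology or any object with a
    ``topology`` attribute holding one (such as the simulator's LineageTree).
    """
    topology = getattr(reference, "topology", reference)
    ref_clusters = _reference_clusters(topology)
    ref_leaves = frozenset().union(*ref_clusters) if ref_clusters else frozenset()
    if ref_leaves != frozenset(dendrogram.leaves):
        raise ValueError(
            f"leaf sets differ: dendrogram {sorted(dendrogram.leaves)} vs "
            f"reference {sorted(ref_leaves)}"
        )
    full = frozenset(dendrogram.leaves)
    n = len(full)
    ref_bip = {
        frozenset({c, full - c}) for c in ref_clusters if 2 <= len(c) <= n - 2
    }
    inf_bip = dendrogram.bipartitions()
    match = {bp: bp in inf_bip for bp in ref_bip}
    unresolved = dendrogram.unresolved
    nested = set(dendrogram.cluster_sets) == set(ref_clusters) and not unresolved
    exact = inf_bip == ref_bip and not unresolved
    return TopologyComparison(inf_bip, ref_bip, match, exact, nested, unresolved)


def has_bipartition(dendrogram: Dendrogram, side: set[str]) -> bool:
    """Whether the dendrogram contains the bipartition side | complement."""
    full = frozenset(dendrogram.leaves)
    bp = frozenset({frozenset(side), full - frozenset(side)})
    return bp in dendrogram.bipartitions() and not dendrogram.unresolved
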