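"""Minimum spanning tree backbones.

Each weighted layer is reduced to its binary MST computed with Kruskal's
algorithm on inverted weights (edge cost 1/w), i.e. the maximum-total-weight
spanning tree of the original weights — the strongest-connection backbone.
Zero-weight pairs are non-edges (never infinite-cost edges), and a
disconnected positive-weight graph is a hard error: the multiplex
construction presumes exactly N-1 links per layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix

__all__ = ["BackboneGraph", "mst_backbone"]


@dataclass
class BackboneGraph:
    """Binary spanning-tree adjacency of one layer."""

    adjacency: np.ndarray
    source_modality: str = ""
    subject_id: str = ""
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a.astype(np.int8)
        n = a.shape[0]
        if self.region_labels:
            self.region_labels = tuple(self.region_labels)
            if len(self.region_labels) != n:
                raise ValueError("region label count does not match adjacency")
        else:
            self.region_labels = tuple(f"R{i:03d}" for i in range(n))
        # tree invariants: N-1 edges and connected (hence acyclic)
        n_edges = int(self.adjacency.sum()) // 2
        if n_edges != n - 1:
            raise ValueError(f"not a spanning tree: {n_edges} edges for N={n}")
        ncomp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        if ncomp != 1:
            raise ValueError(f"not a spanning tree: {ncomp} components")

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def mst_backbone(matrix: ConnectivityMatrix | np.ndarray) -> BackboneGraph:
    """Binary MST backbone of a weighted layer (Kruskal on cost 1/w).

    Ties between equal weights are broken deterministically by the sorted
    (cost, i, j) key, so repeated runs give identical backbones.
    """
    if isinstance(matrix, ConnectivityMatrix):
        w = matrix.weights
        modality, subject_id = matrix.modality, matrix.subject_id
        labels = matrix.region_labels
    else:
        cm = ConnectivityMatrix(np.asarray(matrix, dtype=float))
        w, modality, subject_id, labels = cm.weights, "", "", cm.region_labels
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions")
    ncomp, _ = connected_components(csr_matrix(w > 0), directed=False)
    if ncomp != 1:
        raise ValueError(
            f"positive-weight graph is disconnected ({ncomp} components); "
            "cannot build a spanning tree"
        )
    ii, jj = np.nonzero(np.triu(w, 1) > 0)
    costs = 1.0 / w[ii, jj]
    order = np.lexsort((jj, ii, costs))  # cost asc, then (i, j)
    uf = _UnionFind(n)
    adj = np.zeros((n, n), dtype=np.int8)
    added = 0
    for k in order:
        a, b = int(ii[k]), int(jj[k])
        if uf.union(a, b):
            adj[a, b] = adj[b, a] = 1
            added += 1
            if added == n - 1:
                break
    assert added == n - 1, "internal error: Kruskal terminated early"
    return BackboneGraph(adj, source_modality=modality, subject_id=subject_id,
                         region_labels=labels)
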