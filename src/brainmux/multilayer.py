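"""Multiplex supra-adjacency assembly and centrality.

The L layers (binary MST backbones sharing one node set) are stacked into an
(L*N) x (L*N) supra-adjacency matrix: diagonal blocks hold the intralayer
adjacencies, off-diagonal blocks couple each node only to its own copies in
other layers with a uniform interlayer weight (default 1). Multilayer
eigenvector centrality is the leading eigenvector of this matrix, aggregated
to one score per node by averaging the node's L entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix, identity, bmat
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .atlas import AtlasMapping
from .backbone import BackboneGraph
from .connectivity import ConnectivityMatrix

__all__ = [
    "SupraAdjacency",
    "CentralityVector",
    "build_supra_adjacency",
    "multilayer_ec",
    "single_layer_ec",
    "multilayer_degree",
    "subnetwork_mean",
]

_CLAMP = 1e-12


@dataclass
class CentralityVector:
    """Length-N nonnegative node scores with a method tag."""

    scores: np.ndarray
    method: str
    eigenvalue: float | None = None
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1:
            raise ValueError("scores must be a vector")
        if s.size and s.min() < 0:
            raise ValueError(f"negative centrality score {s.min():.3g}")
        self.scores = s
        if self.region_labels:
            self.region_labels = tuple(self.region_labels)
            if len(self.region_labels) != s.size:
                raise ValueError("region label count does not match scores")


@dataclass
class SupraAdjacency:
    """Sparse (L*N) x (L*N) multiplex supra-adjacency."""

    matrix: csr_matrix
    layer_adjacencies: list[np.ndarray]
    layer_order: tuple[str, ...]
    interlayer_weight: float
    coupling: str
    region_labels: tuple[str, ...]

    @property
    def n_layers(self) -> int:
        return len(self.layer_adjacencies)

    @property
    def n_nodes(self) -> int:
        return self.layer_adjacencies[0].shape[0]

    def intralayer_edge_count(self) -> int:
        return sum(int(a.sum()) // 2 for a in self.layer_adjacencies)

    def interlayer_edge_count(self) -> int:
        intra = 2 * self.intralayer_edge_count()
        return int((self.matrix != 0).sum() - intra) // 2


def build_supra_adjacency(
    layers: Sequence[BackboneGraph],
    interlayer_weight: float = 1.0,
    coupling: str = "categorical",
) -> SupraAdjacency:
    """Stack binary layers into a multiplex supra-adjacency matrix.

    ``coupling="categorical"`` (the default) couples every pair of layers —
    modalities and frequency bands have no natural ordering — while
    ``"chain"`` couples only consecutive layers in ``layers`` order.
    """
    if len(layers) < 1:
        raise ValueError("need at least one layer")
    n = layers[0].n_regions
    labels = layers[0].region_labels
    for lay in layers[1:]:
        if lay.n_regions != n or lay.region_labels != labels:
            raise ValueError(
                "all layers must share the same region count and ordering"
            )
    if coupling not in ("categorical", "chain"):
        raise ValueError(f"unknown coupling topology {coupling!r}")
    L = len(layers)
    eye = identity(n, format="csr") * interlayer_weight
    blocks: list[list] = [[None] * L for _ in range(L)]
    for a in range(L):
        blocks[a][a] = csr_matrix(layers[a].adjacency.astype(float))
        for b in range(a + 1, L):
            coupled = coupling == "categorical" or b == a + 1
            if coupled and interlayer_weight != 0:
                blocks[a][b] = eye
                blocks[b][a] = eye
    supra = bmat(blocks, format="csr")
    order = tuple(lay.source_modality or f"layer{k}" for k, lay in enumerate(layers))
    return SupraAdjacency(supra, [lay.adjacency.copy() for lay in layers],
                          order, float(interlayer_weight), coupling, labels)


def _leading_eigenpair(mat: csr_matrix) -> tuple[float, np.ndarray]:
    """Leading (largest-eigenvalue) eigenpair, deterministically oriented.

    Uses a sparse Lanczos solve with a fixed uniform start vector so repeated
    runs are bit-reproducible; the eigenvector is oriented so its
    largest-magnitude entry is positive and tiny negatives are clamped to 0.
    """
    m = mat.shape[0]
    if m == 1:
        return 0.0, np.ones(1)
    if m == 2:
        val = float(mat[0, 1])
        return abs(val), np.full(2, 1.0 / np.sqrt(2.0))
    v0 = np.ones(m) / np.sqrt(m)
    vals, vecs = eigsh(mat, k=1, which="LA", v0=v0, tol=1e-10, maxiter=10 * m)
    lam = float(vals[0])
    v = vecs[:, 0]
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    v = np.where(np.abs(v) < _CLAMP, 0.0, v)
    v = np.clip(v, 0.0, None)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("leading eigenvector degenerated to zero after clamping")
    return lam, v / nrm


def _require_connected(mat: csr_matrix, what: str) -> None:
    ncomp, _ = connected_components(mat != 0, directed=False)
    if ncomp != 1:
        raise ValueError(
            f"{what} is disconnected ({ncomp} components); the leading "
            "eigenvector is not strictly positive/unique"
        )


def multilayer_ec(supra: SupraAdjacency, mapping: AtlasMapping | None = None) -> CentralityVector:
    """Multilayer eigenvector centrality.

    Leading eigenvector of the supra-adjacency (unit Euclidean norm,
    nonnegative orientation), aggregated from length L*N to length N by
    averaging the entries belonging to the same node. Strictly positive on
    connected supra-graphs by Perron-Frobenius.
    """
    _require_connected(supra.matrix, "supra-adjacency graph")
    lam, v = _leading_eigenpair(supra.matrix)
    scores = v.reshape(supra.n_layers, supra.n_nodes).mean(axis=0)
    if mapping is not None and len(mapping) != supra.n_nodes:
        raise ValueError("atlas mapping size does not match supra-adjacency")
    return CentralityVector(scores, "ec_multilayer", eigenvalue=lam,
                            region_labels=supra.region_labels)


def single_layer_ec(matrix: ConnectivityMatrix | BackboneGraph) -> CentralityVector:
    """Single-layer eigenvector centrality (weighted matrix or binary MST)."""
    if isinstance(matrix, BackboneGraph):
        w = matrix.adjacency.astype(float)
        method = "ec_single_mst"
        labels = matrix.region_labels
    else:
        w = matrix.weights
        method = "ec_single_weighted"
        labels = matrix.region_labels
    sp = csr_matrix(w)
    _require_connected(sp, "graph")
    lam, v = _leading_eigenpair(sp)
    return CentralityVector(v, method, eigenvalue=lam, region_labels=labels)


def multilayer_degree(supra: SupraAdjacency, include_interlayer: bool = False) -> CentralityVector:
    """Overlapping degree: a node's intralayer degree summed across layers.

    Interlayer links are excluded by default — in a multiplex they add the
    same constant to every node and carry no between-node information;
    ``include_interlayer=True`` adds that constant shift back.
    """
    deg = np.zeros(supra.n_nodes)
    for a in supra.layer_adjacencies:
        deg += a.sum(axis=1)
    if include_interlayer:
        L = supra.n_layers
        per_pair = L * (L - 1) if supra.coupling == "categorical" else 2 * (L - 1)
        deg += supra.interlayer_weight * per_pair
    return CentralityVector(deg, "degree_multilayer", region_labels=supra.region_labels)


def subnetwork_mean(cv: CentralityVector, mapping: AtlasMapping, label: str) -> float:
    """Arithmetic mean of the centrality scores over one subnetwork."""
    if len(mapping) != cv.scores.size:
        raise ValueError("atlas mapping size does not match centrality vector")
    mask = mapping.mask(label)
    if not mask.any():
        raise ValueError(f"subnetwork {label!r} is empty")
    return float(cv.scores[mask].mean())
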