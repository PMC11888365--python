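"""Spatial neighborhood graphs: kNN, distance band, Delaunay/Gabriel,
polygon contiguity.

Graphs are undirected and stored with each node pair once. Weights are
binary by default; with ``style="row_standardized"`` the effective weight
matrix normalizes each node's outgoing weights to sum to one (the matrix is
then generally asymmetric, but the underlying adjacency is still stored
once per pair). These graphs are the substrate for exploratory spatial
statistics computed downstream; this package builds and stores them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
import shapely
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import cdist

from .geometry import GeometryLayer

__all__ = [
    "SpatialGraph",
    "graph_knn",
    "graph_distance",
    "graph_delaunay",
    "graph_contiguity",
    "find_spatial_graph",
]

CONTIGUITY_SNAP_TOL = 1e-9


@dataclass
class SpatialGraph:
    """Weighted adjacency over one geometry layer.

    ``edges`` is an (m, 2) int array with i < j, each undirected pair once;
    ``weights`` the matching base weights (before any row standardization).
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray
    style: str = "binary"
    method_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(edges) != len(weights):
            raise ValueError("edges and weights length mismatch")
        if len(edges):
            if edges.min() < 0 or edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if (edges[:, 0] == edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            order = np.lexsort((hi, lo))
            edges = np.column_stack([lo, hi])[order]
            weights = weights[order]
            if (np.diff(edges[:, 0]) == 0).any():
                pairs = edges[:, 0] * self.n_nodes + edges[:, 1]
                if len(np.unique(pairs)) != len(pairs):
                    raise ValueError("duplicate edges")
        if self.style not in ("binary", "row_standardized"):
            raise ValueError(f"unknown style {self.style!r}")
        self.edges = edges
        self.weights = weights

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def weight_matrix(self) -> sp.csr_matrix:
        """Full n x n weight matrix with the style applied.

        Binary style gives the symmetric matrix of base weights; row
        standardization rescales each non-isolated row to sum to 1.
        """
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        w = np.concatenate([self.weights, self.weights])
        W = sp.coo_matrix((w, (i, j)), shape=(self.n_nodes, self.n_nodes)).tocsr()
        if self.style == "row_standardized":
            rowsum = np.asarray(W.sum(axis=1)).ravel()
            scale = np.divide(
                1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0
            )
            W = sp.diags(scale) @ W
        return W

    def neighbor_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            out[i].add(int(j))
            out[j].add(int(i))
        return out

    def subset(self, idx) -> "SpatialGraph":
        """Keep only nodes in ``idx`` (positional, order-preserving) and the
        edges among them; marks the result ``subsetted``."""
        idx = np.asarray(idx, dtype=int)
        remap = -np.ones(self.n_nodes, dtype=int)
        remap[idx] = np.arange(len(idx))
        if len(self.edges):
            a = remap[self.edges[:, 0]]
            b = remap[self.edges[:, 1]]
            keep = (a >= 0) & (b >= 0)
            edges = np.column_stack([a[keep], b[keep]])
            weights = self.weights[keep]
        else:
            edges = np.empty((0, 2), dtype=int)
            weights = np.empty(0)
        meta = dict(self.method_meta)
        meta["subsetted"] = True
        return SpatialGraph(len(idx), edges, weights, self.style, meta)

    def to_json(self) -> str:
        payload = {
            "n_nodes": int(self.n_nodes),
            "edges": [
                [int(i), int(j), float(w)]
                for (i, j), w in zip(self.edges, self.weights)
            ],
            "style": self.style,
            "method_meta": self.method_meta,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SpatialGraph":
        d = json.loads(text)
        arr = np.asarray(d["edges"], dtype=float).reshape(-1, 3)
        return cls(
            d["n_nodes"],
            arr[:, :2].astype(int),
            arr[:, 2],
            d["style"],
            d.get("method_meta", {}),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpatialGraph):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and self.style == other.style
            and np.array_equal(self.edges, other.edges)
            and np.allclose(self.weights, other.weights)
        )


def _points_of(layer: GeometryLayer) -> np.ndarray:
    if layer.family != "point":
        raise ValueError(f"expected a point layer, got {layer.family!r}")
    return shapely.get_coordinates(layer.geometry)


def _make(n, pairs, method, params, layer_name=None) -> SpatialGraph:
    pairs = sorted({(min(i, j), max(i, j)) for i, j in pairs})
    edges = np.array(pairs, dtype=int).reshape(-1, 2)
    meta = {
        "method": method,
        "params": params,
        "layer": layer_name,
        "subsetted": False,
    }
    return SpatialGraph(n, edges, np.ones(len(edges)), "binary", meta)


def graph_knn(
    points: GeometryLayer, k: int, symmetrize: str = "union"
) -> SpatialGraph:
    """k-nearest-neighbor graph, symmetrized.

    Directed kNN sets under Euclidean distance; exact-distance ties are
    broken toward the lower index. ``symmetrize="union"`` keeps an edge if
    either endpoint selects the other; ``"mutual"`` requires both.
    """
    xy = _points_of(points)
    n = len(xy)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    if symmetrize not in ("union", "mutual"):
        raise ValueError("symmetrize must be 'union' or 'mutual'")
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    # stable argsort breaks exact-distance ties toward the lower index
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    directed = {(i, int(j)) for i in range(n) for j in order[i]}
    if symmetrize == "union":
        pairs = {(min(i, j), max(i, j)) for i, j in directed}
    else:
        pairs = {
            (min(i, j), max(i, j)) for i, j in directed if (j, i) in directed
        }
    return _make(n, pairs, "knn", {"k": k, "symmetrize": symmetrize})


def graph_distance(points: GeometryLayer, d_max: float) -> SpatialGraph:
    """Distance-band graph: edge iff Euclidean distance <= d_max (inclusive).
    Isolated nodes are allowed."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    xy = _points_of(points)
    n = len(xy)
    d = cdist(xy, xy)
    ii, jj = np.nonzero(np.triu(d <= d_max, k=1))
    return _make(n, zip(ii.tolist(), jj.tolist()), "distance", {"d_max": d_max})


def graph_delaunay(points: GeometryLayer, prune: str = "none") -> SpatialGraph:
    """Delaunay triangulation edges, optionally pruned to the Gabriel graph.

    The Gabriel graph keeps edge (i, j) only when the open disk whose
    diameter is the segment ij contains no other point.
    """
    if prune not in ("none", "gabriel"):
        raise ValueError("prune must be 'none' or 'gabriel'")
    xy = _points_of(points)
    n = len(xy)
    if n < 3:
        raise ValueError("Delaunay triangulation needs at least 3 points")
    try:
        tri = Delaunay(xy)
    except QhullError as e:
        raise ValueError(
            "Delaunay triangulation failed: points are collinear or "
            "degenerate"
        ) from e
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            pairs.add((min(i, j), max(i, j)))
    if prune == "gabriel":
        kept = set()
        for i, j in pairs:
            mid = 0.5 * (xy[i] + xy[j])
            r2 = 0.25 * np.sum((xy[i] - xy[j]) ** 2)
            d2 = np.sum((xy - mid) ** 2, axis=1)
            d2[[i, j]] = np.inf
            if not (d2 < r2).any():  # open disk: boundary points allowed
                kept.add((i, j))
        pairs = kept
    return _make(n, pairs, "delaunay", {"prune": prune})


def graph_contiguity(polygons: GeometryLayer) -> SpatialGraph:
    """Queen-style polygon contiguity: edge iff two polygons share at least
    one boundary point, detected within a small snap tolerance."""
    if polygons.family != "polygon":
        raise ValueError(f"expected a polygon layer, got {polygons.family!r}")
    n = len(polygons)
    tree = shapely.STRtree(polygons.geometry)
    ii, jj = tree.query(
        polygons.geometry, predicate="dwithin", distance=CONTIGUITY_SNAP_TOL
    )
    pairs = {(min(a, b), max(a, b)) for a, b in zip(ii.tolist(), jj.tolist()) if a != b}
    return _make(n, pairs, "contiguity", {"snap_tol": CONTIGUITY_SNAP_TOL})


_METHODS = {
    "knn": graph_knn,
    "distance": graph_distance,
    "delaunay": graph_delaunay,
    "contiguity": graph_contiguity,
}


def find_spatial_graph(
    container,
    scope: str,
    layer: str,
    method: str,
    params: dict | None = None,
    graph_name: str | None = None,
    style: str = "binary",
):
    """Build a spatial graph from a container's geometry layer and store it.

    ``scope`` is "col" or "annot"; the graph lands in ``col_graphs`` or
    ``annot_graphs`` under ``graph_name`` (default: the method name),
    overwriting any previous graph of that name. With
    ``style="row_standardized"`` the effective weights of every
    non-isolated node sum to one.
    """
    if scope not in ("col", "annot"):
        raise ValueError("scope must be 'col' or 'annot'")
    if method not in _METHODS:
        raise ValueError(f"unknown graph method {method!r}")
    geom = container.get_geometry(scope, layer)
    g = _METHODS[method](geom, **(params or {}))
    g.style = style
    g.method_meta["layer"] = layer
    container.set_graph(scope, graph_name or method, g)
    return container
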