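"""Spatial aggregation: regular grids, binning cell-level matrices, and
counting transcript spots into polygons to form new count matrices.

Every aggregation assigns each cell (via an assignment point, by default
the centroid of its column geometry) or transcript spot to at most one bin:
a point on a shared bin boundary goes to the lowest bin index, so touching
bins never double-count. With ``fun="sum"`` and bins covering all
assignment points, per-gene totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely

from .container import SpatialFeatureContainer, new_container
from .geometry import GeometryLayer, SpatialExtent

__all__ = [
    "GridSpec",
    "make_grid",
    "assign_points_to_polygons",
    "count_points_in_polygons",
    "aggregate_cells",
    "aggregate_transcripts",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid specification.

    ``cellsize`` is the square side length, or for hexagons the
    center-to-center horizontal spacing between adjacent columns of
    flat-topped hexagons (circumradius = cellsize / 1.5). ``origin``
    anchors the grid; None snaps it to the extent's lower-left corner.
    """

    kind: str = "square"
    cellsize: float = 1.0
    origin: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("square", "hex"):
            raise ValueError(f"grid kind must be 'square' or 'hex', got {self.kind!r}")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")


def make_grid(extent: SpatialExtent, spec: GridSpec) -> GeometryLayer:
    """Tile an extent with square or flat-topped hexagonal cells.

    The tiling covers the extent completely; boundary cells may overhang.
    Cells are pairwise interior-disjoint. Attributes carry the cell's
    (column, row) grid indices.
    """
    ox, oy = spec.origin if spec.origin is not None else (extent.xmin, extent.ymin)
    cs = spec.cellsize
    geoms: list[shapely.Polygon] = []
    cols_idx: list[int] = []
    rows_idx: list[int] = []
    if spec.kind == "square":
        i0 = int(np.floor((extent.xmin - ox) / cs))
        i1 = int(np.ceil((extent.xmax - ox) / cs))
        j0 = int(np.floor((extent.ymin - oy) / cs))
        j1 = int(np.ceil((extent.ymax - oy) / cs))
        for j in range(j0, j1):
            for i in range(i0, i1):
                geoms.append(
                    shapely.box(ox + i * cs, oy + j * cs, ox + (i + 1) * cs, oy + (j + 1) * cs)
                )
                cols_idx.append(i)
                rows_idx.append(j)
    else:
        # flat-topped hexagons: column pitch = cs, circumradius R = cs/1.5,
        # vertical pitch sqrt(3)*R, odd columns offset by half a pitch
        R = cs / 1.5
        vert = np.sqrt(3.0) * R
        angles = np.deg2rad(np.arange(0, 360, 60))
        hx = R * np.cos(angles)
        hy = R * np.sin(angles)
        i0 = int(np.floor((extent.xmin - ox - R) / cs))
        i1 = int(np.ceil((extent.xmax - ox + R) / cs))
        j0 = int(np.floor((extent.ymin - oy - vert) / vert))
        j1 = int(np.ceil((extent.ymax - oy + vert) / vert))
        for i in range(i0, i1 + 1):
            yoff = 0.5 * vert if (i % 2) else 0.0
            cx = ox + i * cs
            for j in range(j0, j1 + 1):
                cy = oy + j * vert + yoff
                geoms.append(shapely.Polygon(np.column_stack([cx + hx, cy + hy])))
                cols_idx.append(i)
                rows_idx.append(j)
        # drop cells that cannot touch the extent (keeps output compact)
        box = extent.as_polygon()
        keep = shapely.intersects(np.array(geoms, dtype=object), box)
        geoms = [g for g, k in zip(geoms, keep) if k]
        cols_idx = [v for v, k in zip(cols_idx, keep) if k]
        rows_idx = [v for v, k in zip(rows_idx, keep) if k]
    attrs = pd.DataFrame({"grid_col": cols_idx, "grid_row": rows_idx})
    return GeometryLayer(geoms, attrs, validate=False)


def assign_points_to_polygons(xy: np.ndarray, polygons: GeometryLayer) -> np.ndarray:
    """Assign each point to at most one polygon (inside or on boundary).

    Returns an int array of polygon indices, -1 for unassigned points.
    Boundary ties resolve to the lowest polygon index.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    assign = np.full(len(xy), -1, dtype=int)
    if not len(xy) or not len(polygons):
        return assign
    pts = shapely.points(xy)
    tree = shapely.STRtree(pts)
    for j in range(len(polygons) - 1, -1, -1):
        hits = tree.query(polygons.geometry[j], predicate="intersects")
        assign[hits] = j  # descending j: the lowest index wins ties
    return assign


def count_points_in_polygons(
    points: GeometryLayer, polygons: GeometryLayer, label_col: str = "gene"
) -> tuple[sp.csr_matrix, pd.Index]:
    """Count labeled points per polygon into a sparse (labels x polygons)
    matrix. Each point counts at most once (lowest polygon index on
    boundary ties); points outside all polygons contribute nowhere.
    Returns the matrix and the label order (first appearance).
    """
    if label_col not in points.attributes.columns:
        raise KeyError(f"label column {label_col!r} missing from point layer")
    if points.family not in (None, "point"):
        raise ValueError("points layer must hold point geometries")
    labels = pd.Index(pd.unique(points.attributes[label_col]))
    xy_parts = []
    lab_idx_parts = []
    codes = labels.get_indexer(points.attributes[label_col])
    for g, code in zip(points.geometry, codes):
        if g.is_empty:
            continue
        coords = shapely.get_coordinates(g)
        xy_parts.append(coords)
        lab_idx_parts.append(np.full(len(coords), code))
    if xy_parts:
        xy = np.concatenate(xy_parts)
        lab = np.concatenate(lab_idx_parts)
        assign = assign_points_to_polygons(xy, polygons)
        ok = assign >= 0
        mat = sp.coo_matrix(
            (np.ones(ok.sum(), dtype=np.int64), (lab[ok], assign[ok])),
            shape=(len(labels), len(polygons)),
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(labels), len(polygons)), dtype=np.int64)
    return mat, labels


def _assignment_points(c: SpatialFeatureContainer, colgeom: str | None) -> np.ndarray:
    if colgeom is None:
        for name, layer in c.col_geometries.items():
            if layer.family == "point":
                return layer.centroids()
        for name, layer in c.col_geometries.items():
            return layer.centroids()
        raise ValueError(
            "container has no column geometry to derive assignment points from"
        )
    return c.get_geometry("col", colgeom).centroids()


def aggregate_cells(
    c: SpatialFeatureContainer,
    by: GeometryLayer,
    fun: str | Callable = "sum",
    assay: str = "counts",
    colgeom: str | None = None,
) -> SpatialFeatureContainer:
    """Aggregate a cell-level matrix into bins.

    Each cell is assigned to the bin containing its assignment point (the
    centroid of ``colgeom``; polygonal cell geometries reduce to their
    centroids). ``fun`` is "sum", "mean", or any callable mapping a numeric
    vector to a scalar, applied per gene per bin. Cells outside all bins
    are dropped; their number is recorded in the result's
    ``metadata["n_cells_outside"]``. The bin polygons become the new
    column geometry "bins".
    """
    X = c.assay(assay)
    pts = _assignment_points(c, colgeom)
    assign = assign_points_to_polygons(pts, by)
    n_bins = len(by)
    if callable(fun):
        fname = getattr(fun, "__name__", "custom")
        f = fun
    else:
        fname = fun
        f = {"sum": np.sum, "mean": np.mean, "min": np.min, "max": np.max}.get(fun)
        if f is None:
            raise ValueError(
                "fun must be callable or one of 'sum', 'mean', 'min', 'max'"
            )
    if not callable(fun) and fun == "sum":
        ok = assign >= 0
        ind = sp.coo_matrix(
            (np.ones(ok.sum()), (np.nonzero(ok)[0], assign[ok])),
            shape=(c.n_locations, n_bins),
        ).tocsr()
        if sp.issparse(X):
            out_X = sp.csr_matrix(X @ ind).astype(X.dtype)
        else:
            out_X = (np.asarray(X) @ ind.toarray()).astype(X.dtype)
    else:
        Xd = X.toarray() if sp.issparse(X) else np.asarray(X)
        out_X = np.zeros((c.n_features, n_bins))
        for b in range(n_bins):
            members = np.nonzero(assign == b)[0]
            if len(members):
                sub = Xd[:, members]
                out_X[:, b] = np.array([f(row) for row in sub])
    col_meta = by.attributes.copy()
    out = SpatialFeatureContainer(
        {assay: out_X}, row_meta=c.row_meta.copy(), col_meta=col_meta, units=c.units
    )
    out.set_geometry("col", "bins", by.copy())
    out.annot_geometries = {k: v.copy() for k, v in c.annot_geometries.items()}
    out.images = {k: v.copy() for k, v in c.images.items()}
    out.metadata = {
        "aggregated_from": assay,
        "fun": fname,
        "n_cells_outside": int((assign < 0).sum()),
    }
    return out


def aggregate_transcripts(
    c: SpatialFeatureContainer,
    by: GeometryLayer,
    rowgeom: str = "spots",
) -> SpatialFeatureContainer:
    """Count per-gene transcript spots into bins, forming a new count
    matrix aligned to the container's features.

    The container's row geometry ``rowgeom`` must hold one (multi)point per
    gene; genes with empty multipoints yield all-zero rows. Columns of the
    result are the bin geometries (new column geometry "bins").
    """
    if rowgeom not in c.row_geometries:
        raise ValueError(
            f"container has no row geometry {rowgeom!r} holding transcript spots"
        )
    spots = c.row_geometries[rowgeom]
    xy_parts, gene_parts = [], []
    for gi, g in enumerate(spots.geometry):
        if g.is_empty:
            continue
        coords = shapely.get_coordinates(g)
        xy_parts.append(coords)
        gene_parts.append(np.full(len(coords), gi))
    if xy_parts:
        xy = np.concatenate(xy_parts)
        gene = np.concatenate(gene_parts)
        assign = assign_points_to_polygons(xy, by)
        ok = assign >= 0
        X = sp.coo_matrix(
            (np.ones(ok.sum(), dtype=np.int64), (gene[ok], assign[ok])),
            shape=(c.n_features, len(by)),
        ).tocsr()
    else:
        X = sp.csr_matrix((c.n_features, len(by)), dtype=np.int64)
    out = SpatialFeatureContainer(
        {"counts": X},
        row_meta=c.row_meta.copy(),
        col_meta=by.attributes.copy(),
        units=c.units,
    )
    out.set_geometry("col", "bins", by.copy())
    out.metadata = {"aggregated_from": f"row_geometries/{rowgeom}"}
    return out
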