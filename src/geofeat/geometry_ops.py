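"""Whole-container spatial operations: affine transforms, cropping,
predicate joins between layers, annotation summaries, and splitting.

All operations treat the container as a stack of co-registered map layers:
a transform moves every geometry and image together; a crop selects matrix
columns by a spatial predicate against a column geometry while clipping
annotations and images to the query region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry.base import BaseGeometry

from .container import SpatialFeatureContainer
from .geometry import GeometryLayer, SpatialExtent
from .transforms import AffineTransform, affine_named

__all__ = [
    "transform_container",
    "named_transform",
    "crop",
    "relate",
    "annot_summary",
    "split_by_annotation",
]

_PREDICATES = {"intersects", "contains", "within", "touches", "covered_by"}


def named_transform(
    c: SpatialFeatureContainer, kind: str, center="bbox", **params
) -> AffineTransform:
    """Named transform for a container; ``center="bbox"`` (the default)
    pivots mirror/transpose/scale/rotate about the container's bounding-box
    center so the footprint stays in place."""
    if isinstance(center, str):
        if center != "bbox":
            raise ValueError(f"center must be a point or 'bbox', got {center!r}")
        center = c.bbox().center
    return affine_named(kind, center=center, **params)


def _transform_layer(layer: GeometryLayer, T: AffineTransform) -> GeometryLayer:
    geoms = [T.apply_geometry(g) for g in layer.geometry]
    return GeometryLayer(geoms, layer.attributes.copy(), validate=False)


def transform_container(
    c: SpatialFeatureContainer, T: AffineTransform, resample: str = "bilinear"
) -> SpatialFeatureContainer:
    """Apply one affine map to every geometry layer and every image.

    Axis-aligned transforms move images exactly (pixel permutation plus a
    new extent; lazy images stay lazy with the ops queued); general
    affines resample image pixels. Relative alignment between layers is
    preserved because the identical map is applied everywhere.
    """
    out = c.copy()
    for gm in (out.col_geometries, out.row_geometries, out.annot_geometries):
        for name in list(gm):
            gm[name] = _transform_layer(gm[name], T)
    for name in list(out.images):
        out.images[name] = out.images[name].affine(T, resample=resample)
    return out


def _query_geom(query) -> BaseGeometry:
    if isinstance(query, SpatialExtent):
        return query.as_polygon()
    if isinstance(query, BaseGeometry):
        return query
    if isinstance(query, (tuple, list)) and len(query) == 4:
        return SpatialExtent(*query).as_polygon()
    raise TypeError(
        "query must be a shapely geometry, a SpatialExtent, or a 4-tuple"
    )


def _col_predicate(
    layer: GeometryLayer, query: BaseGeometry, predicate: str
) -> np.ndarray:
    if predicate == "intersects":
        return shapely.intersects(layer.geometry, query)
    if predicate == "contains_in":
        return shapely.within(layer.geometry, query)
    if predicate == "covered_by":
        return shapely.covered_by(layer.geometry, query)
    raise ValueError(
        "crop predicate must be 'intersects', 'contains_in' or 'covered_by'"
    )


def _keep_family(geom: BaseGeometry, family: str) -> BaseGeometry | None:
    """Drop degenerate pieces so a clipped layer stays type-homogeneous."""
    wanted = {
        "point": ("Point", "MultiPoint"),
        "line": ("LineString", "MultiLineString"),
        "polygon": ("Polygon", "MultiPolygon"),
    }[family]
    if geom.is_empty:
        return None
    if geom.geom_type in wanted:
        return geom
    if geom.geom_type == "GeometryCollection":
        parts = [g for g in geom.geoms if g.geom_type in wanted and not g.is_empty]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return shapely.union_all(parts)
    return None


def crop(
    c: SpatialFeatureContainer,
    query,
    colgeom: str = "centroids",
    predicate: str = "intersects",
    annot_op: str = "clip",
) -> SpatialFeatureContainer:
    """Spatially crop the container to a region of interest.

    Matrix columns are kept iff ``predicate`` holds between their geometry
    in layer ``colgeom`` and the query (a shapely geometry, extent, or
    bbox 4-tuple); the synchronized-subset contract then filters everything
    aligned to columns. Annotation layers are clipped by geometric
    intersection (``annot_op="clip"``, empty and degenerate pieces
    dropped) or kept whole iff intersecting (``"keep_whole"``). Images are
    cropped to the query's bounding box; images disjoint from it are
    dropped. A query touching nothing yields a valid zero-column container.
    """
    if annot_op not in ("clip", "keep_whole"):
        raise ValueError("annot_op must be 'clip' or 'keep_whole'")
    q = _query_geom(query)
    layer = c.get_geometry("col", colgeom)
    keep = _col_predicate(layer, q, predicate)
    out = c.subset(None, np.nonzero(keep)[0])
    for name in list(out.annot_geometries):
        lay = out.annot_geometries[name]
        if annot_op == "keep_whole":
            hit = np.nonzero(shapely.intersects(lay.geometry, q))[0]
            out.annot_geometries[name] = lay.take(hit)
        else:
            fam = lay.family
            geoms, rows = [], []
            for i, g in enumerate(lay.geometry):
                clipped = _keep_family(shapely.intersection(g, q), fam)
                if clipped is not None:
                    geoms.append(clipped)
                    rows.append(i)
            out.annot_geometries[name] = GeometryLayer(
                geoms, lay.attributes.iloc[rows], validate=False
            )
    qext = SpatialExtent.from_bounds(shapely.bounds(q))
    for name in list(out.images):
        img = out.images[name]
        if img.extent.intersection(qext) is None:
            del out.images[name]
        else:
            out.images[name] = img.crop(qext)
    return out


def relate(
    a: GeometryLayer, b: GeometryLayer, predicate: str = "intersects"
) -> sp.csr_matrix:
    """Sparse boolean |a| x |b| relation: entry (i, j) is True iff
    ``predicate(a_i, b_j)`` holds, with standard simple-features semantics
    (boundary contact counts for intersects/touches)."""
    if predicate not in _PREDICATES - {"covered_by"}:
        raise ValueError(
            "predicate must be 'intersects', 'contains', 'within' or 'touches'"
        )
    if len(a) == 0 or len(b) == 0:
        raise ValueError("relate requires two non-empty layers")
    tree = shapely.STRtree(b.geometry)
    ai, bj = tree.query(a.geometry, predicate=predicate)
    data = np.ones(len(ai), dtype=bool)
    return sp.coo_matrix(
        (data, (ai, bj)), shape=(len(a), len(b)), dtype=bool
    ).tocsr()


def annot_summary(
    c: SpatialFeatureContainer,
    annot: str,
    colgeom: str,
    attribute: str | None = None,
    fun: str = "mean",
) -> np.ndarray:
    """Per-column summary of an annotation attribute over intersecting
    annotation geometries (e.g. mean myofiber area per spot).

    Columns intersecting no annotation geometry get NaN, except
    ``fun="count"`` which gives 0. ``attribute`` is ignored for count.
    """
    funs = {
        "mean": np.mean,
        "sum": np.sum,
        "count": len,
        "min": np.min,
        "max": np.max,
    }
    if fun not in funs:
        raise ValueError(f"fun must be one of {sorted(funs)}")
    ann = c.get_geometry("annot", annot)
    cols = c.get_geometry("col", colgeom)
    if fun != "count":
        if attribute is None or attribute not in ann.attributes.columns:
            raise KeyError(
                f"attribute {attribute!r} not found in annot layer {annot!r} "
                f"(available: {list(ann.attributes.columns)})"
            )
        values = ann.attributes[attribute].to_numpy()
    rel = relate(cols, ann, "intersects").tolil()
    out = np.full(len(cols), np.nan)
    for i in range(len(cols)):
        hits = rel.rows[i]
        if fun == "count":
            out[i] = len(hits)
        elif hits:
            out[i] = funs[fun](values[list(hits)])
    return out


def split_by_annotation(
    c: SpatialFeatureContainer,
    annot: str,
    colgeom: str,
    predicate: str = "intersects",
    name_col: str | None = None,
) -> dict[str, SpatialFeatureContainer]:
    """One sub-container per annotation geometry (e.g. histological
    region), holding the columns satisfying the predicate with it.

    A column matching several regions appears in each of them. Containers
    are keyed by the annotation layer's ``name_col`` attribute (default:
    a "name" or "id" column if present, else the geometry index as a
    string).
    """
    ann = c.get_geometry("annot", annot)
    if len(ann) == 0:
        raise ValueError(f"annot layer {annot!r} is empty")
    if name_col is None:
        for cand in ("name", "id"):
            if cand in ann.attributes.columns:
                name_col = cand
                break
    if name_col is not None:
        names = ann.attributes[name_col].astype(str).tolist()
    else:
        names = [str(i) for i in range(len(ann))]
    cols = c.get_geometry("col", colgeom)
    rel = relate(cols, ann, predicate).tocsc()
    out: dict[str, SpatialFeatureContainer] = {}
    for j, name in enumerate(names):
        members = rel.getcol(j).tocoo().row
        out[name] = c.subset(None, np.sort(members))
    return out
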