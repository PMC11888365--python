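"""The spatial feature container: a gene-count matrix aligned with vector
geometry layers, spatial neighborhood graphs, per-location statistic
results, and extent-registered raster images, all in one Cartesian
coordinate frame.

The frame is y-up Cartesian; raster row 0 is the top of the image
(y = ymax). Geometry layers attach to matrix columns (locations: spots or
cells), matrix rows (features: e.g. per-gene transcript multipoints), or to
nothing (annotations: tissue boundaries, histological regions). Subsetting
the matrix filters every aligned structure in lock-step: column geometry
layers, per-location local-statistic results, and column graphs all follow
the column selection; row geometry layers follow the row selection.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geometry import GeometryLayer, SpatialExtent
from .graphs import SpatialGraph
from .images import ImageLayer

__all__ = ["SpatialFeatureContainer", "new_container"]

_AXES = ("col", "row", "annot")


def _matrix_shape(m) -> tuple[int, int]:
    if sp.issparse(m):
        return m.shape
    return np.asarray(m).shape


class SpatialFeatureContainer:
    """Count matrix plus aligned spatial layers.

    Use :func:`new_container` (or the readers / fixture generators) to
    build one; then attach layers with the setters. All setters validate
    the alignment invariants: column layers and graphs must match
    ``n_locations``, row layers ``n_features``, local-results matrices
    ``n_locations``.
    """

    FORMAT_VERSION = "1.0"

    def __init__(
        self,
        assays: Mapping[str, np.ndarray | sp.spmatrix],
        row_meta: pd.DataFrame,
        col_meta: pd.DataFrame,
        units: str = "full_res_pixel",
    ):
        assays = dict(assays)
        if not assays:
            raise ValueError("at least one assay is required")
        shapes = {name: _matrix_shape(m) for name, m in assays.items()}
        first = next(iter(shapes.values()))
        for name, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"assay {name!r} has shape {shp}, expected {first}"
                )
        n_features, n_locations = first
        row_meta = pd.DataFrame(row_meta).reset_index(drop=True)
        col_meta = pd.DataFrame(col_meta).reset_index(drop=True)
        if len(row_meta) != n_features:
            raise ValueError(
                f"row_meta has {len(row_meta)} rows but assays have "
                f"{n_features} features (row axis mismatch)"
            )
        if len(col_meta) != n_locations:
            raise ValueError(
                f"col_meta has {len(col_meta)} rows but assays have "
                f"{n_locations} locations (column axis mismatch)"
            )
        self.assays = assays
        self.row_meta = row_meta
        self.col_meta = col_meta
        self.units = units
        self.col_geometries: dict[str, GeometryLayer] = {}
        self.row_geometries: dict[str, GeometryLayer] = {}
        self.annot_geometries: dict[str, GeometryLayer] = {}
        self.col_graphs: dict[str, SpatialGraph] = {}
        self.annot_graphs: dict[str, SpatialGraph] = {}
        self.local_results: dict[str, dict[str, pd.DataFrame]] = {}
        self.images: dict[str, ImageLayer] = {}
        self.metadata: dict = {}

    # -- basic dims --------------------------------------------------------
    @property
    def n_features(self) -> int:
        return _matrix_shape(next(iter(self.assays.values())))[0]

    @property
    def n_locations(self) -> int:
        return _matrix_shape(next(iter(self.assays.values())))[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_features, self.n_locations)

    def assay(self, name: str = "counts"):
        if name not in self.assays:
            raise KeyError(f"no assay named {name!r}")
        return self.assays[name]

    # -- geometry getters/setters -----------------------------------------
    def _geom_map(self, axis: str) -> dict[str, GeometryLayer]:
        if axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
        return {
            "col": self.col_geometries,
            "row": self.row_geometries,
            "annot": self.annot_geometries,
        }[axis]

    def set_geometry(self, axis: str, name: str, layer: GeometryLayer) -> "SpatialFeatureContainer":
        n = {"col": self.n_locations, "row": self.n_features}.get(axis)
        if n is not None and len(layer) != n:
            raise ValueError(
                f"{axis} geometry layer {name!r} has {len(layer)} rows; the "
                f"container has {n} {'locations' if axis == 'col' else 'features'}"
            )
        self._geom_map(axis)[name] = layer
        return self

    def get_geometry(self, axis: str, name: str) -> GeometryLayer:
        gm = self._geom_map(axis)
        if name not in gm:
            raise KeyError(
                f"no {axis} geometry layer named {name!r} "
                f"(available: {sorted(gm)})"
            )
        return gm[name]

    # -- graphs ------------------------------------------------------------
    def _graph_map(self, scope: str) -> dict[str, SpatialGraph]:
        if scope == "col":
            return self.col_graphs
        if scope == "annot":
            return self.annot_graphs
        raise ValueError(f"graph scope must be 'col' or 'annot', got {scope!r}")

    def set_graph(self, scope: str, name: str, graph: SpatialGraph) -> "SpatialFeatureContainer":
        if scope == "col" and graph.n_nodes != self.n_locations:
            raise ValueError(
                f"col graph {name!r} has {graph.n_nodes} nodes; the "
                f"container has {self.n_locations} locations"
            )
        if scope == "annot":
            layer = graph.method_meta.get("layer")
            if layer is not None and layer in self.annot_geometries:
                n = len(self.annot_geometries[layer])
                if graph.n_nodes != n:
                    raise ValueError(
                        f"annot graph {name!r} has {graph.n_nodes} nodes but "
                        f"its layer {layer!r} has {n} geometries"
                    )
        self._graph_map(scope)[name] = graph
        return self

    def get_graph(self, scope: str, name: str) -> SpatialGraph:
        gm = self._graph_map(scope)
        if name not in gm:
            raise KeyError(f"no {scope} graph named {name!r} (available: {sorted(gm)})")
        return gm[name]

    # -- local results -----------------------------------------------------
    def set_local_result(
        self, statistic: str, feature: str, values
    ) -> "SpatialFeatureContainer":
        """Store a per-location statistic matrix (n_locations x k, named
        columns such as "stat", "p_value") under (statistic, feature)."""
        df = pd.DataFrame(values).reset_index(drop=True)
        df.columns = [str(col) for col in df.columns]  # CSV-stable names
        if len(df) != self.n_locations:
            raise ValueError(
                f"local result for ({statistic!r}, {feature!r}) has "
                f"{len(df)} rows; the container has {self.n_locations} locations"
            )
        self.local_results.setdefault(statistic, {})[feature] = df
        return self

    def get_local_result(self, statistic: str, feature: str) -> pd.DataFrame:
        if statistic not in self.local_results:
            raise KeyError(
                f"no local results for statistic {statistic!r} "
                f"(available: {sorted(self.local_results)})"
            )
        per_feat = self.local_results[statistic]
        if feature not in per_feat:
            raise KeyError(
                f"statistic {statistic!r} has no results for feature "
                f"{feature!r} (available: {sorted(per_feat)})"
            )
        return per_feat[feature]

    # -- images ------------------------------------------------------------
    def set_image(self, name: str, image: ImageLayer) -> "SpatialFeatureContainer":
        self.images[name] = image
        return self

    def get_image(self, name: str) -> ImageLayer:
        if name not in self.images:
            raise KeyError(f"no image named {name!r} (available: {sorted(self.images)})")
        return self.images[name]

    # -- extent ------------------------------------------------------------
    def bbox(self) -> SpatialExtent:
        """Smallest axis-aligned rectangle covering every geometry layer
        and every image extent."""
        extents: list[SpatialExtent] = []
        for gm in (self.col_geometries, self.row_geometries, self.annot_geometries):
            for layer in gm.values():
                if any(not g.is_empty for g in layer.geometry):
                    extents.append(layer.bounds())
        for img in self.images.values():
            extents.append(img.extent)
        if not extents:
            raise ValueError("container has no geometry layers or images; bbox undefined")
        out = extents[0]
        for e in extents[1:]:
            out = out.union(e)
        return out

    # -- subsetting --------------------------------------------------------
    @staticmethod
    def _check_idx(idx, n: int, axis: str) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        if idx.ndim != 1:
            raise ValueError(f"{axis} index must be one-dimensional")
        if len(idx) and (idx.min() < -n or idx.max() >= n):
            raise IndexError(f"{axis} index out of range for size {n}")
        idx = np.where(idx < 0, idx + n, idx)
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"duplicate indices in {axis} selection are not allowed")
        return idx

    def subset(self, row_idx=None, col_idx=None) -> "SpatialFeatureContainer":
        """Select features (rows) and/or locations (columns), filtering
        every aligned structure consistently.

        Column graphs keep only surviving nodes and the edges among them
        (flagged ``subsetted``); row-standardized weights renormalize over
        surviving neighbors. Annotation layers, annotation graphs, and
        images pass through unchanged.
        """
        ri = (
            np.arange(self.n_features)
            if row_idx is None
            else self._check_idx(row_idx, self.n_features, "row")
        )
        ci = (
            np.arange(self.n_locations)
            if col_idx is None
            else self._check_idx(col_idx, self.n_locations, "col")
        )
        assays = {}
        for name, m in self.assays.items():
            if sp.issparse(m):
                assays[name] = m.tocsr()[ri][:, ci]
            else:
                assays[name] = np.asarray(m)[np.ix_(ri, ci)]
        out = SpatialFeatureContainer(
            assays,
            self.row_meta.iloc[ri],
            self.col_meta.iloc[ci],
            units=self.units,
        )
        out.col_geometries = {k: v.take(ci) for k, v in self.col_geometries.items()}
        out.row_geometries = {k: v.take(ri) for k, v in self.row_geometries.items()}
        out.annot_geometries = {k: v.copy() for k, v in self.annot_geometries.items()}
        out.col_graphs = {k: g.subset(ci) for k, g in self.col_graphs.items()}
        out.annot_graphs = {k: g for k, g in self.annot_graphs.items()}
        out.local_results = {
            stat: {
                feat: df.iloc[ci].reset_index(drop=True)
                for feat, df in per_feat.items()
            }
            for stat, per_feat in self.local_results.items()
        }
        out.images = {k: img.copy() for k, img in self.images.items()}
        out.metadata = dict(self.metadata)
        return out

    def copy(self) -> "SpatialFeatureContainer":
        return self.subset(None, None)

    def __repr__(self) -> str:
        return (
            f"SpatialFeatureContainer({self.n_features} features x "
            f"{self.n_locations} locations; assays={sorted(self.assays)}, "
            f"col_geometries={sorted(self.col_geometries)}, "
            f"row_geometries={sorted(self.row_geometries)}, "
            f"annot_geometries={sorted(self.annot_geometries)}, "
            f"col_graphs={sorted(self.col_graphs)}, "
            f"annot_graphs={sorted(self.annot_graphs)}, "
            f"images={sorted(self.images)}, units={self.units!r})"
        )


def new_container(
    counts,
    col_meta: pd.DataFrame | None = None,
    row_meta: pd.DataFrame | None = None,
    units: str = "full_res_pixel",
) -> SpatialFeatureContainer:
    """Build a container from a counts matrix and metadata tables.

    ``counts`` is features x locations (dense or scipy sparse). Omitted
    metadata tables default to empty tables of the right length.
    """
    n_features, n_locations = _matrix_shape(counts)
    if row_meta is None:
        row_meta = pd.DataFrame(index=pd.RangeIndex(n_features))
    if col_meta is None:
        col_meta = pd.DataFrame(index=pd.RangeIndex(n_locations))
    return SpatialFeatureContainer(
        {"counts": counts}, row_meta=row_meta, col_meta=col_meta, units=units
    )
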