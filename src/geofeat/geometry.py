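"""Vector geometry primitives: spatial extents and simple-features layers.

A :class:`GeometryLayer` is the basic vector unit of the container: a
homogeneous column of 2-D simple-features geometries (points, lines or
polygons, single or multi) plus an attribute table with one row per
geometry, in the spirit of an ``sf`` data frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = ["SpatialExtent", "GeometryLayer"]


@dataclass(frozen=True)
class SpatialExtent:
    """Axis-aligned rectangle (xmin, ymin, xmax, ymax) in container units."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"invalid extent: need xmin < xmax and ymin < ymax, got "
                f"({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def as_polygon(self) -> shapely.Polygon:
        return shapely.box(self.xmin, self.ymin, self.xmax, self.ymax)

    def union(self, other: "SpatialExtent") -> "SpatialExtent":
        return SpatialExtent(
            min(self.xmin, other.xmin),
            min(self.ymin, other.ymin),
            max(self.xmax, other.xmax),
            max(self.ymax, other.ymax),
        )

    def intersection(self, other: "SpatialExtent") -> "SpatialExtent | None":
        """Overlap rectangle, or None when the extents are disjoint."""
        xmin, ymin = max(self.xmin, other.xmin), max(self.ymin, other.ymin)
        xmax, ymax = min(self.xmax, other.xmax), min(self.ymax, other.ymax)
        if xmin >= xmax or ymin >= ymax:
            return None
        return SpatialExtent(xmin, ymin, xmax, ymax)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    @classmethod
    def from_bounds(cls, bounds: Sequence[float]) -> "SpatialExtent":
        return cls(*map(float, bounds))


# base geometry type -> layer family; a layer may mix single and multi
# variants of the same family (clipping a polygon can yield a multipolygon)
_FAMILY = {
    "Point": "point",
    "MultiPoint": "point",
    "LineString": "line",
    "MultiLineString": "line",
    "Polygon": "polygon",
    "MultiPolygon": "polygon",
}


class GeometryLayer:
    """A homogeneous list of 2-D simple features plus per-geometry attributes.

    Parameters
    ----------
    geometry
        Iterable of shapely geometries, all of one family (point-like,
        line-like, or polygon-like). Empty geometries (e.g. an empty
        multipoint for a gene with no transcript spots) are allowed.
    attributes
        Optional table with one row per geometry. A fresh RangeIndex is
        imposed so positional and label indexing agree.
    validate
        Check coordinate finiteness and polygon validity. Disable only for
        layers produced by operations that already guarantee validity.
    """

    def __init__(
        self,
        geometry: Iterable[BaseGeometry],
        attributes: pd.DataFrame | None = None,
        validate: bool = True,
    ):
        geoms = np.empty(0, dtype=object)
        glist = list(geometry)
        if glist:
            geoms = np.array(glist, dtype=object)
        self.geometry = geoms
        if attributes is None:
            attributes = pd.DataFrame(index=pd.RangeIndex(len(geoms)))
        else:
            attributes = pd.DataFrame(attributes).reset_index(drop=True)
        if len(attributes) != len(geoms):
            raise ValueError(
                f"attribute table has {len(attributes)} rows but layer has "
                f"{len(geoms)} geometries"
            )
        self.attributes = attributes
        self._family = self._check_family()
        if validate:
            self._validate()

    def _check_family(self) -> str | None:
        families = {_FAMILY.get(g.geom_type) for g in self.geometry}
        if None in families:
            bad = {g.geom_type for g in self.geometry} - set(_FAMILY)
            raise ValueError(f"unsupported geometry types in layer: {sorted(bad)}")
        if len(families) > 1:
            raise ValueError(
                f"layer mixes geometry families {sorted(families)}; layers "
                "must be homogeneous (point-like, line-like or polygon-like)"
            )
        return families.pop() if families else None

    def _validate(self) -> None:
        for i, g in enumerate(self.geometry):
            if g.is_empty:
                continue
            if not np.isfinite(shapely.bounds(g)).all():
                raise ValueError(f"geometry {i} has non-finite coordinates")
            if self._family == "polygon" and not g.is_valid:
                raise ValueError(
                    f"geometry {i} is an invalid polygon "
                    f"({shapely.is_valid_reason(g)})"
                )

    def __len__(self) -> int:
        return len(self.geometry)

    @property
    def family(self) -> str | None:
        """'point', 'line' or 'polygon' (None for an empty layer)."""
        return self._family

    def take(self, idx) -> "GeometryLayer":
        """Positional subset, preserving the order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return GeometryLayer(
            self.geometry[idx],
            self.attributes.iloc[idx],
            validate=False,
        )

    def bounds(self) -> SpatialExtent:
        """Tight axis-aligned extent of all non-empty geometries."""
        nonempty = [g for g in self.geometry if not g.is_empty]
        if not nonempty:
            raise ValueError("layer has no non-empty geometries")
        b = shapely.bounds(np.array(nonempty, dtype=object))
        xmin, ymin = b[:, 0].min(), b[:, 1].min()
        xmax, ymax = b[:, 2].max(), b[:, 3].max()
        # degenerate (single point) extents are padded to stay valid
        if xmin == xmax:
            xmin, xmax = xmin - 0.5, xmax + 0.5
        if ymin == ymax:
            ymin, ymax = ymin - 0.5, ymax + 0.5
        return SpatialExtent(xmin, ymin, xmax, ymax)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of geometry centroids (identity for points)."""
        cent = shapely.centroid(self.geometry)
        return shapely.get_coordinates(cent)

    def copy(self) -> "GeometryLayer":
        return GeometryLayer(
            self.geometry.copy(), self.attributes.copy(), validate=False
        )

    def __eq__(self, other) -> bool:  # exact structural equality, for tests
        if not isinstance(other, GeometryLayer):
            return NotImplemented
        if len(self) != len(other):
            return False
        same_geoms = all(
            shapely.equals_exact(a, b, tolerance=0.0)
            for a, b in zip(self.geometry, other.geometry)
        )
        return same_geoms and self.attributes.equals(other.attributes)

    def __repr__(self) -> str:
        cols = list(self.attributes.columns)
        return (
            f"GeometryLayer({len(self)} {self._family or 'empty'} "
            f"geometries, attributes={cols})"
        )
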