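"""Equality assertions for containers and layers, for use in test suites
and round-trip checks."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import shapely

from .container import SpatialFeatureContainer
from .geometry import GeometryLayer
from .images import ImageLayer

__all__ = [
    "assert_layers_equal",
    "assert_images_equal",
    "assert_containers_equal",
]


def assert_layers_equal(a: GeometryLayer, b: GeometryLayer, msg: str = "") -> None:
    assert len(a) == len(b), f"{msg}: layer lengths {len(a)} != {len(b)}"
    for i, (ga, gb) in enumerate(zip(a.geometry, b.geometry)):
        assert shapely.equals_exact(ga, gb, tolerance=0.0), (
            f"{msg}: geometry {i} differs"
        )
    assert list(a.attributes.columns) == list(b.attributes.columns), (
        f"{msg}: attribute columns differ"
    )
    for col in a.attributes.columns:
        va, vb = a.attributes[col].to_numpy(), b.attributes[col].to_numpy()
        if va.dtype.kind == "f":
            assert np.array_equal(va, vb, equal_nan=True), f"{msg}: column {col}"
        else:
            assert (va == vb).all(), f"{msg}: column {col}"


def assert_images_equal(a: ImageLayer, b: ImageLayer, msg: str = "") -> None:
    assert a.extent.as_tuple() == b.extent.as_tuple(), f"{msg}: extents differ"
    pa, pb = a.materialize().pixels, b.materialize().pixels
    assert pa.shape == pb.shape, f"{msg}: shapes {pa.shape} != {pb.shape}"
    assert np.array_equal(pa, pb), f"{msg}: pixel values differ"


def _dense(m) -> np.ndarray:
    return m.toarray() if sp.issparse(m) else np.asarray(m)


def assert_containers_equal(
    a: SpatialFeatureContainer, b: SpatialFeatureContainer
) -> None:
    """Assert every component of two containers matches: assays exactly,
    metadata tables by value, geometry coordinates bit-exactly, graphs as
    edge sets with weights, local results by value, image pixels and
    extents exactly."""
    assert a.shape == b.shape, f"shapes {a.shape} != {b.shape}"
    assert a.units == b.units
    assert sorted(a.assays) == sorted(b.assays)
    for name in a.assays:
        assert np.array_equal(_dense(a.assays[name]), _dense(b.assays[name])), (
            f"assay {name} differs"
        )
    for which, ma, mb in (("row_meta", a.row_meta, b.row_meta), ("col_meta", a.col_meta, b.col_meta)):
        assert list(ma.columns) == list(mb.columns), f"{which} columns differ"
        for col in ma.columns:
            va, vb = ma[col].to_numpy(), mb[col].to_numpy()
            if va.dtype.kind == "f":
                assert np.allclose(va, vb, equal_nan=True), f"{which}.{col}"
            else:
                assert (va == vb).all(), f"{which}.{col}"
    for axis in ("col", "row", "annot"):
        ga, gb = a._geom_map(axis), b._geom_map(axis)
        assert sorted(ga) == sorted(gb), f"{axis} geometry names differ"
        for name in ga:
            assert_layers_equal(ga[name], gb[name], f"{axis} geometry {name}")
    for scope in ("col", "annot"):
        ma, mb = a._graph_map(scope), b._graph_map(scope)
        assert sorted(ma) == sorted(mb), f"{scope} graph names differ"
        for name in ma:
            assert ma[name] == mb[name], f"{scope} graph {name} differs"
    assert sorted(a.local_results) == sorted(b.local_results)
    for stat in a.local_results:
        assert sorted(a.local_results[stat]) == sorted(b.local_results[stat])
        for feat, df in a.local_results[stat].items():
            other = b.local_results[stat][feat]
            assert list(df.columns) == list(other.columns)
            assert np.allclose(
                df.to_numpy(dtype=float), other.to_numpy(dtype=float), equal_nan=True
            ), f"local result ({stat}, {feat}) differs"
    assert sorted(a.images) == sorted(b.images)
    for name in a.images:
        assert_images_equal(a.images[name], b.images[name], f"image {name}")
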