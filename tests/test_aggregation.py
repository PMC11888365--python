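"""Grids and aggregation: coverage, conservation, and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import shapely

import geofeat as gf
from geofeat import GeometryLayer, GridSpec, SpatialExtent


def _brute_assign(xy, polygons):
    """Reference assignment: lowest polygon index containing each point."""
    out = np.full(len(xy), -1, dtype=int)
    for i, (x, y) in enumerate(xy):
        p = shapely.Point(x, y)
        for j, poly in enumerate(polygons.geometry):
            if poly.intersects(p):
                out[i] = j
                break
    return out


class TestMakeGrid:
    def test_square_grid_cell_count_and_area(self):
        grid = gf.make_grid(SpatialExtent(0, 0, 2, 2), GridSpec("square", 1))
        assert len(grid) == 4
        assert all(g.area == pytest.approx(1.0) for g in grid.geometry)

    def test_square_grid_overhang(self):
        grid = gf.make_grid(SpatialExtent(0, 0, 2.5, 1), GridSpec("square", 1))
        assert len(grid) == 3

    def test_hex_grid_covers_extent(self):
        extent = SpatialExtent(0, 0, 50, 40)
        grid = gf.make_grid(extent, GridSpec("hex", 7))
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [rng.uniform(0, 50, 1000), rng.uniform(0, 40, 1000)]
        )
        covered = np.zeros(len(pts), dtype=bool)
        for g in grid.geometry:
            covered |= shapely.intersects_xy(g, pts[:, 0], pts[:, 1])
        assert covered.all()

    @pytest.mark.parametrize("kind", ["square", "hex"])
    def test_cells_interior_disjoint(self, kind):
        cs = 5.0
        grid = gf.make_grid(SpatialExtent(0, 0, 21, 17), GridSpec(kind, cs))
        geoms = grid.geometry
        tree = shapely.STRtree(geoms)
        ii, jj = tree.query(geoms, predicate="intersects")
        for a, b in zip(ii, jj):
            if a < b:
                overlap = geoms[a].intersection(geoms[b]).area
                assert overlap < 1e-9 * cs**2

    def test_bad_cellsize_rejected(self):
        with pytest.raises(ValueError, match="cellsize"):
            GridSpec("square", 0)

    def test_hex_horizontal_spacing_is_cellsize(self):
        grid = gf.make_grid(SpatialExtent(0, 0, 40, 10), GridSpec("hex", 8))
        attrs = grid.attributes
        cents = grid.centroids()
        row0 = cents[(attrs["grid_row"] == 0) & (attrs["grid_col"] % 2 == 0)]
        xs = np.sort(row0[:, 0])
        assert np.allclose(np.diff(xs), 16.0)  # every-other column: 2 * cellsize


class TestAggregateCells:
    def _container(self, coords, counts):
        c = gf.new_container(np.asarray(counts))
        c.set_geometry(
            "col", "centroids", GeometryLayer([shapely.Point(p) for p in coords])
        )
        return c

    def test_sum_two_bins(self):
        c = self._container([(0.5, 0.5), (0.6, 0.5), (1.5, 0.5)], [[1, 2, 5]])
        bins = GeometryLayer([shapely.box(0, 0, 1, 1), shapely.box(1, 0, 2, 1)])
        out = gf.aggregate_cells(c, bins, fun="sum")
        X = out.assay()
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
        assert X.tolist() == [[3, 5]]

    def test_sum_conserves_per_gene_totals(self, small_container):
        c = small_container
        grid = gf.make_grid(c.bbox(), GridSpec("square", 150))
        out = gf.aggregate_cells(c, grid, fun="sum", colgeom="centroids")
        assert out.metadata["n_cells_outside"] == 0
        tot_in = np.asarray(c.assay().sum(axis=1)).ravel()
        tot_out = np.asarray(out.assay().sum(axis=1)).ravel()
        assert np.array_equal(tot_in, tot_out)

    def test_max_matches_brute_force(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 10, size=(50, 2))
        counts = rng.poisson(3, size=(4, 50))
        c = self._container(coords, counts)
        bins = GeometryLayer(
            [shapely.box(0, 0, 5, 5), shapely.box(5, 0, 10, 5),
             shapely.box(0, 5, 5, 10), shapely.box(5, 5, 10, 10)]
        )
        out = gf.aggregate_cells(c, bins, fun="max")
        assign = _brute_assign(coords, bins)
        expected = np.zeros((4, 4))
        for b in range(4):
            members = np.nonzero(assign == b)[0]
            if len(members):
                expected[:, b] = counts[:, members].max(axis=1)
        assert np.array_equal(np.asarray(out.assay()), expected)

    def test_polygon_col_geometry_reduces_to_centroid(self, small_container):
        grid = gf.make_grid(small_container.bbox(), GridSpec("square", 300))
        out = gf.aggregate_cells(small_container, grid, fun="sum", colgeom="cellSeg")
        assert out.n_locations == len(grid)

    def test_missing_col_geometry_rejected(self):
        c = gf.new_container(np.zeros((1, 2)))
        bins = GeometryLayer([shapely.box(0, 0, 1, 1)])
        with pytest.raises(ValueError):
            gf.aggregate_cells(c, bins, fun="sum")


class TestCountPoints:
    def test_single_point_in_unit_square(self):
        pts = GeometryLayer(
            [shapely.Point(0.5, 0.5)], pd.DataFrame({"gene": ["A"]})
        )
        polys = GeometryLayer([shapely.box(0, 0, 1, 1)])
        mat, labels = gf.count_points_in_polygons(pts, polys)
        assert mat.toarray().tolist() == [[1]]
        assert labels.tolist() == ["A"]

    def test_outside_points_contribute_nowhere(self):
        pts = GeometryLayer(
            [shapely.Point(0.5, 0.5), shapely.Point(2, 2)],
            pd.DataFrame({"gene": ["A", "A"]}),
        )
        polys = GeometryLayer([shapely.box(0, 0, 1, 1)])
        mat, _ = gf.count_points_in_polygons(pts, polys)
        assert mat.sum() == 1

    def test_boundary_tie_goes_to_lowest_index(self):
        pts = GeometryLayer(
            [shapely.Point(1, 0.5)], pd.DataFrame({"gene": ["A"]})
        )
        polys = GeometryLayer([shapely.box(0, 0, 1, 1), shapely.box(1, 0, 2, 1)])
        mat, _ = gf.count_points_in_polygons(pts, polys)
        assert mat.toarray().tolist() == [[1, 0]]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        xy = rng.uniform(0, 10, size=(500, 2))
        genes = rng.choice(["A", "B", "C"], size=500)
        pts = GeometryLayer(
            [shapely.Point(p) for p in xy], pd.DataFrame({"gene": genes})
        )
        polys = GeometryLayer(
            [shapely.box(0, 0, 4, 4), shapely.box(5, 0, 9, 4),
             shapely.box(0, 5, 4, 9), shapely.box(5, 5, 9, 9)]
        )
        mat, labels = gf.count_points_in_polygons(pts, polys)
        assign = _brute_assign(xy, polys)
        expected = np.zeros((3, 4), dtype=int)
        code = {g: i for i, g in enumerate(labels)}
        for g, a in zip(genes, assign):
            if a >= 0:
                expected[code[g], a] += 1
        assert np.array_equal(mat.toarray(), expected)


class TestAggregateTranscripts:
    def test_spotless_gene_gives_zero_row(self, small_container):
        c = small_container
        empties = [i for i, g in enumerate(c.row_geometries["spots"].geometry)]
        grid = gf.make_grid(c.bbox(), GridSpec("square", 200))
        out = gf.aggregate_transcripts(c, grid)
        X = out.assay().toarray()
        spots = c.row_geometries["spots"].geometry
        for i in empties:
            if spots[i].is_empty:
                assert X[i].sum() == 0

    def test_total_equals_spots_in_bins(self, small_container):
        c = small_container
        grid = gf.make_grid(c.bbox(), GridSpec("hex", 180))
        out = gf.aggregate_transcripts(c, grid)
        n_spots = sum(
            len(shapely.get_coordinates(g))
            for g in c.row_geometries["spots"].geometry
        )
        # hex grid covers the container bbox, hence all spots
        assert out.assay().sum() == n_spots

    def test_hex_bins_match_brute_force(self, small_container):
        c = small_container.subset(np.arange(4), None)
        grid = gf.make_grid(c.bbox(), GridSpec("hex", 250))
        out = gf.aggregate_transcripts(c, grid)
        expected = np.zeros((c.n_features, len(grid)), dtype=int)
        for gi, geom in enumerate(c.row_geometries["spots"].geometry):
            coords = shapely.get_coordinates(geom)
            assign = _brute_assign(coords, grid)
            for a in assign:
                if a >= 0:
                    expected[gi, a] += 1
        assert np.array_equal(out.assay().toarray(), expected)

    def test_missing_row_geometry_rejected(self):
        c = gf.new_container(np.zeros((1, 2)))
        grid = GeometryLayer([shapely.box(0, 0, 1, 1)])
        with pytest.raises(ValueError, match="row geometry"):
            gf.aggregate_transcripts(c, grid)
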