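"""Raster layers: lazy loading, axis ops, affine resampling, pixel
extraction, downsampling and cropping."""

import json

import numpy as np
import pandas as pd
import pytest
import shapely
import tifffile

import geofeat as gf
from geofeat import AffineTransform, GeometryLayer, ImageLayer, SpatialExtent
from geofeat import affine_named, load_image


@pytest.fixture
def gradient_image():
    xs = np.linspace(0, 1, 60)
    ys = np.linspace(0, 1, 40)
    px = 100 * xs[None, :] + 50 * ys[:, None]
    return ImageLayer(px, SpatialExtent(0, 0, 60, 40))


@pytest.fixture
def tiff_file(tmp_path):
    rng = np.random.default_rng(12)
    px = rng.integers(0, 255, size=(10, 20), dtype=np.uint8)
    path = tmp_path / "img.tiff"
    tifffile.imwrite(path, px)
    return path, px


class TestLoad:
    def test_lazy_header_only(self, tiff_file):
        path, px = tiff_file
        img = load_image(path, SpatialExtent(0, 0, 20, 10), lazy=True)
        assert img.is_lazy
        assert (img.width, img.height, img.n_channels) == (20, 10, 1)
        assert img.pixels is None

    def test_lazy_png_header(self, tmp_path):
        from PIL import Image as PILImage

        px = np.zeros((10, 20), dtype=np.uint8)
        path = tmp_path / "img.png"
        PILImage.fromarray(px, mode="L").save(path)
        img = load_image(path, SpatialExtent(0, 0, 20, 10), lazy=True)
        assert (img.width, img.height) == (20, 10)

    def test_sidecar_extent(self, tiff_file, tmp_path):
        path, _ = tiff_file
        sidecar = {"xmin": 0, "ymin": 0, "xmax": 40, "ymax": 20}
        (tmp_path / "img.tiff.extent.json").write_text(json.dumps(sidecar))
        img = load_image(path)
        assert img.extent.as_tuple() == (0, 0, 40, 20)

    def test_missing_extent_and_sidecar_errors(self, tiff_file):
        path, _ = tiff_file
        with pytest.raises(ValueError, match="extent"):
            load_image(path)

    def test_eager_load_matches_file(self, tiff_file):
        path, px = tiff_file
        img = load_image(path, SpatialExtent(0, 0, 20, 10))
        assert np.array_equal(img.pixels, px)


class TestMaterialize:
    def test_double_mirror_is_identity(self, tiff_file):
        path, px = tiff_file
        img = load_image(path, SpatialExtent(0, 0, 20, 10), lazy=True)
        out = img.axis_op("mirror_v").axis_op("mirror_v").materialize()
        assert np.array_equal(out.pixels, px)

    def test_no_queue_equals_eager(self, tiff_file):
        path, px = tiff_file
        lazy = load_image(path, SpatialExtent(0, 0, 20, 10), lazy=True)
        assert np.array_equal(lazy.materialize().pixels, px)

    def test_transpose_swaps_dims(self, tiff_file):
        path, px = tiff_file
        lazy = load_image(path, SpatialExtent(0, 0, 20, 10), lazy=True)
        out = lazy.axis_op("transpose")
        assert out.is_lazy
        assert (out.nrows, out.ncols) == (20, 10)
        assert out.materialize().pixels.shape == (20, 10)

    def test_lazy_queue_equals_eager_sequence(self, tiff_file):
        path, px = tiff_file
        ops = ["mirror_h", "transpose", "mirror_v", "transpose", "mirror_h"]
        lazy = load_image(path, SpatialExtent(0, 0, 20, 10), lazy=True)
        eager = ImageLayer(px, SpatialExtent(0, 0, 20, 10))
        for op in ops:
            lazy = lazy.axis_op(op)
            eager = eager.axis_op(op)
        assert lazy.is_lazy
        out = lazy.materialize()
        assert np.array_equal(out.pixels, eager.pixels)
        assert out.extent.as_tuple() == eager.extent.as_tuple()


class TestAxisOps:
    def test_mirror_h_moves_first_column_last(self):
        px = np.arange(6).reshape(2, 3)
        img = ImageLayer(px, SpatialExtent(0, 0, 3, 2))
        out = img.axis_op("mirror_h")
        assert np.array_equal(out.pixels, px[:, ::-1])
        assert out.extent.as_tuple() == (0, 0, 3, 2)

    def test_transpose_extent_swaps_about_center(self):
        img = ImageLayer(np.zeros((2, 4)), SpatialExtent(0, 0, 4, 2))
        out = img.axis_op("transpose")
        # center stays (2, 1); width/height swap
        assert out.extent.as_tuple() == (1, -1, 3, 3)
        assert out.pixels.shape == (4, 2)

    def test_mean_preserved_exactly(self, tiff_file):
        path, px = tiff_file
        img = load_image(path, SpatialExtent(0, 0, 20, 10))
        for op in ("mirror_h", "mirror_v", "transpose"):
            assert img.axis_op(op).pixels.mean() == px.mean()


class TestAffine:
    def test_identity_nearest_is_bit_identical(self, tiff_file):
        path, px = tiff_file
        img = load_image(path, SpatialExtent(0, 0, 20, 10))
        out = img.affine(AffineTransform.identity(), resample="nearest")
        assert np.array_equal(out.pixels, px)

    def test_rot90_constant_image_stays_constant(self):
        img = ImageLayer(np.full((10, 20), 7.0), SpatialExtent(0, 0, 20, 10))
        T = affine_named("rotate", center=img.extent.center, angle=90)
        out = img.affine(T)
        assert out.pixels.shape == (20, 10)
        assert np.allclose(out.pixels, 7.0)

    def test_rotation_round_trip_small_error(self, gradient_image):
        # rotate by a non-axis-aligned angle and back; the result lives on
        # a regridded raster, so compare mean values over interior boxes
        T = affine_named("rotate", center=gradient_image.extent.center, angle=41)
        out = gradient_image.affine(T).affine(T.inverse())
        boxes = GeometryLayer(
            [shapely.box(10 + 6 * i, 10, 16 + 6 * i, 30) for i in range(5)]
        )
        before = gradient_image.extract(boxes, "mean")
        after = out.extract(boxes, "mean")
        dyn = gradient_image.pixels.max() - gradient_image.pixels.min()
        assert np.abs(after - before).mean() < 0.02 * dyn

    def test_coregistration_with_geometry(self, gradient_image):
        # extracting under a polygon commutes with transforming both
        poly = GeometryLayer([shapely.box(10, 5, 40, 30)])
        before = gradient_image.extract(poly, "mean")[0]
        T = affine_named("rotate", center=(11, 3), angle=28)
        img_t = gradient_image.affine(T)
        poly_t = GeometryLayer([T.apply_geometry(poly.geometry[0])])
        after = img_t.extract(poly_t, "mean")[0]
        dyn = gradient_image.pixels.max() - gradient_image.pixels.min()
        assert abs(after - before) < 0.03 * dyn


class TestExtract:
    def test_constant_image_mean(self):
        img = ImageLayer(np.full((8, 8), 7.0), SpatialExtent(0, 0, 8, 8))
        poly = GeometryLayer([shapely.box(1, 1, 5, 6)])
        assert img.extract(poly, "mean")[0] == 7.0

    def test_left_half_of_two_by_two(self):
        img = ImageLayer(np.array([[1.0, 2.0], [3.0, 4.0]]), SpatialExtent(0, 0, 2, 2))
        poly = GeometryLayer([shapely.box(0, 0, 1, 2)])
        assert img.extract(poly, "mean")[0] == pytest.approx(2.0)

    def test_point_gets_containing_pixel(self):
        img = ImageLayer(np.array([[1.0, 2.0], [3.0, 4.0]]), SpatialExtent(0, 0, 2, 2))
        pts = GeometryLayer([shapely.Point(1.5, 0.5), shapely.Point(0.2, 1.9)])
        out = img.extract(pts)
        assert out.tolist() == [4.0, 1.0]

    def test_outside_geometry_gives_nan(self):
        img = ImageLayer(np.ones((4, 4)), SpatialExtent(0, 0, 4, 4))
        poly = GeometryLayer([shapely.box(10, 10, 12, 12)])
        assert np.isnan(img.extract(poly, "mean")[0])

    def test_sum_matches_pixel_center_brute_force(self):
        rng = np.random.default_rng(14)
        px = rng.uniform(0, 10, size=(30, 30))
        img = ImageLayer(px, SpatialExtent(0, 0, 30, 30))
        polys = []
        for _ in range(20):
            cx, cy = rng.uniform(3, 27, 2)
            pts = np.column_stack(
                [cx + rng.uniform(-3, 3, 5), cy + rng.uniform(-3, 3, 5)]
            )
            polys.append(shapely.convex_hull(shapely.MultiPoint(pts)))
        layer = GeometryLayer(polys)
        got = img.extract(layer, "sum")
        xs, ys = img.pixel_centers()
        for gi, poly in enumerate(polys):
            total, any_hit = 0.0, False
            for r, y in enumerate(ys):
                for cc, x in enumerate(xs):
                    if poly.intersects(shapely.Point(x, y)):
                        total += px[r, cc]
                        any_hit = True
            if any_hit:
                assert got[gi] == pytest.approx(total)
            else:
                assert np.isnan(got[gi])

    def test_multichannel_returns_per_channel(self):
        px = np.stack([np.ones((4, 4)), 2 * np.ones((4, 4))], axis=-1)
        img = ImageLayer(px, SpatialExtent(0, 0, 4, 4))
        out = img.extract(GeometryLayer([shapely.box(0, 0, 4, 4)]), "mean")
        assert out.shape == (1, 2)
        assert out.tolist() == [[1.0, 2.0]]


class TestDownsampleCrop:
    def test_factor_one_is_identity(self, tiff_file):
        path, px = tiff_file
        img = load_image(path, SpatialExtent(0, 0, 20, 10))
        assert np.array_equal(img.downsample(1).pixels, px)

    def test_constant_image_downsampled(self):
        img = ImageLayer(np.full((4, 4), 3.0), SpatialExtent(0, 0, 4, 4))
        out = img.downsample(2)
        assert out.pixels.shape == (2, 2)
        assert np.allclose(out.pixels, 3.0)
        assert out.extent.as_tuple() == (0, 0, 4, 4)

    def test_mean_preserved_for_divisible_dims(self):
        rng = np.random.default_rng(15)
        px = rng.uniform(size=(8, 12))
        img = ImageLayer(px, SpatialExtent(0, 0, 12, 8))
        assert img.downsample(4).pixels.mean() == pytest.approx(px.mean())

    def test_partial_edge_blocks_are_partial_means(self):
        px = np.arange(6.0).reshape(2, 3)
        img = ImageLayer(px, SpatialExtent(0, 0, 3, 2))
        out = img.downsample(2)
        assert out.pixels.shape == (1, 2)
        assert out.pixels[0, 0] == pytest.approx(np.mean([0, 1, 3, 4]))
        assert out.pixels[0, 1] == pytest.approx(np.mean([2, 5]))

    def test_crop_left_half(self):
        px = np.arange(24.0).reshape(4, 6)
        img = ImageLayer(px, SpatialExtent(0, 0, 6, 4))
        out = img.crop(SpatialExtent(0, 0, 3, 4))
        assert out.pixels.shape == (4, 3)
        assert np.array_equal(out.pixels, px[:, :3])
        assert out.extent.as_tuple() == (0, 0, 3, 4)

    def test_disjoint_crop_errors(self):
        img = ImageLayer(np.zeros((4, 4)), SpatialExtent(0, 0, 4, 4))
        with pytest.raises(ValueError, match="disjoint"):
            img.crop(SpatialExtent(10, 10, 12, 12))
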