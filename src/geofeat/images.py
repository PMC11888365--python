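"""Extent-registered raster images, in-memory or lazy file-backed.

An image is a pixel grid placed in the container's Cartesian frame by a
:class:`~geofeat.geometry.SpatialExtent`. The frame is y-up and pixel row 0
is the TOP row of the image (y = ymax): column ``c`` has center
``x = xmin + (c + 0.5) * width / ncols`` and row ``r`` has center
``y = ymax - (r + 0.5) * height / nrows``.

Two flavors exist. In-memory images hold the pixel array. Lazy images hold
a file path plus cached dimensions and answer all metadata queries (width,
height, extent) without touching pixel data; axis-aligned operations on
them are queued and only replayed when :meth:`ImageLayer.materialize` is
called, mirroring metadata-only image handling for files too large to load
eagerly.
"""

from __future__ import annotations

import json
import os
from typing import Callable

import numpy as np
import shapely
import tifffile
from PIL import Image as PILImage

from .geometry import GeometryLayer, SpatialExtent
from .transforms import AffineTransform, affine_named

__all__ = ["ImageLayer", "load_image"]

# queued lazy ops are pure pixel-array permutations; the extent is tracked
# live on the layer, so replaying the queue never needs coordinate math
_PIXEL_OPS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "fliplr": lambda a: a[:, ::-1].copy(),
    "flipud": lambda a: a[::-1].copy(),
    # anti-transpose: new[r', c'] = old[r, c] with r' = ncols-1-c, c' = nrows-1-r,
    # which is what the map (x, y) -> (y, x) does to a y-up raster
    "antitranspose": lambda a: a.swapaxes(0, 1)[::-1, ::-1].copy(),
}

_EXTRACT_FUNS = {"mean": np.mean, "sum": np.sum, "min": np.min, "max": np.max}


def _read_pixels(path: str) -> np.ndarray:
    if str(path).lower().endswith((".tif", ".tiff")):
        return np.asarray(tifffile.imread(path))
    return np.asarray(PILImage.open(path))


def _read_header(path: str) -> tuple[int, int, int]:
    """(nrows, ncols, channels) without loading pixel data."""
    if str(path).lower().endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            shape = tf.pages[0].shape
        if len(shape) == 2:
            return shape[0], shape[1], 1
        return shape[0], shape[1], shape[2]
    with PILImage.open(path) as im:  # PIL defers pixel decoding
        w, h = im.size
        ch = len(im.getbands())
    return h, w, ch


class ImageLayer:
    """Raster pixels registered to a spatial extent.

    Build in-memory layers with the constructor and file-backed ones with
    :func:`load_image`. Grayscale arrays are (nrows, ncols); multichannel
    arrays are (nrows, ncols, channels).
    """

    def __init__(self, pixels: np.ndarray, extent: SpatialExtent):
        pixels = np.asarray(pixels)
        if pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D (grayscale) or 3-D (channels)")
        self.pixels: np.ndarray | None = pixels
        self.extent = extent
        self.path: str | None = None
        self.queue: list[str] = []
        self._shape = (
            pixels.shape[0],
            pixels.shape[1],
            1 if pixels.ndim == 2 else pixels.shape[2],
        )

    @classmethod
    def _lazy(cls, path: str, extent: SpatialExtent) -> "ImageLayer":
        obj = cls.__new__(cls)
        obj.pixels = None
        obj.extent = extent
        obj.path = str(path)
        obj.queue = []
        obj._shape = _read_header(path)
        return obj

    # -- metadata (never loads pixels) -----------------------------------
    @property
    def is_lazy(self) -> bool:
        return self.pixels is None

    @property
    def nrows(self) -> int:
        return self._shape[0]

    @property
    def ncols(self) -> int:
        return self._shape[1]

    @property
    def width(self) -> int:
        return self._shape[1]

    @property
    def height(self) -> int:
        return self._shape[0]

    @property
    def n_channels(self) -> int:
        return self._shape[2]

    @property
    def pixel_size(self) -> tuple[float, float]:
        """(dx, dy): spatial size of one pixel."""
        return (self.extent.width / self.ncols, self.extent.height / self.nrows)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x centers (per column) and y centers (per row,
        top row first)."""
        dx, dy = self.pixel_size
        xs = self.extent.xmin + (np.arange(self.ncols) + 0.5) * dx
        ys = self.extent.ymax - (np.arange(self.nrows) + 0.5) * dy
        return xs, ys

    def copy(self) -> "ImageLayer":
        if self.is_lazy:
            out = ImageLayer._lazy(self.path, self.extent)
            out.queue = list(self.queue)
            out._shape = self._shape
            return out
        return ImageLayer(self.pixels.copy(), self.extent)

    # -- lazy/eager conversion -------------------------------------------
    def materialize(self) -> "ImageLayer":
        """In-memory layer with any queued axis ops applied, in order."""
        if not self.is_lazy:
            return self
        px = _read_pixels(self.path)
        for op in self.queue:
            px = _PIXEL_OPS[op](px)
        return ImageLayer(px, self.extent)

    # -- axis-aligned ops --------------------------------------------------
    def _apply_pixel_op(self, op: str, extent: SpatialExtent) -> "ImageLayer":
        if self.is_lazy:
            out = self.copy()
            out.queue.append(op)
            out.extent = extent
            if op == "antitranspose":
                r, c, ch = out._shape
                out._shape = (c, r, ch)
            return out
        return ImageLayer(_PIXEL_OPS[op](self.pixels), extent)

    def axis_op(self, op: str) -> "ImageLayer":
        """Mirror or transpose about the image's own extent center.

        ``mirror_h`` flips left-right, ``mirror_v`` up-down (both keep the
        extent), ``transpose`` maps (x, y) -> (y, x) about the center
        (extent width/height swap in place). Lazy inputs stay lazy: the op
        is queued and only metadata is updated.
        """
        if op not in ("mirror_h", "mirror_v", "transpose"):
            raise ValueError(f"unknown axis op {op!r}")
        T = affine_named(op, center=self.extent.center)
        return self.apply_axis_aligned(T)

    def apply_axis_aligned(self, T: AffineTransform) -> "ImageLayer":
        """Apply an axis-aligned affine exactly, by permuting pixels and
        remapping the extent; no resampling, lazy inputs stay lazy."""
        if not T.is_axis_aligned:
            raise ValueError("transform is not axis-aligned; use affine()")
        e = self.extent
        corners = np.array(
            [[e.xmin, e.ymin], [e.xmin, e.ymax], [e.xmax, e.ymin], [e.xmax, e.ymax]]
        )
        tc = T(corners)
        new_extent = SpatialExtent(
            tc[:, 0].min(), tc[:, 1].min(), tc[:, 0].max(), tc[:, 1].max()
        )
        M = T.M
        out = self
        if M[0, 0] == 0:  # anti-diagonal: x' = b*y, y' = c*x
            out = out._apply_pixel_op("antitranspose", new_extent)
            b, c = M[0, 1], M[1, 0]
            if b < 0:
                out = out._apply_pixel_op("fliplr", new_extent)
            if c < 0:
                out = out._apply_pixel_op("flipud", new_extent)
        else:
            a, d = M[0, 0], M[1, 1]
            if a < 0 and d < 0:
                out = out._apply_pixel_op("fliplr", new_extent)
                out = out._apply_pixel_op("flipud", new_extent)
            elif a < 0:
                out = out._apply_pixel_op("fliplr", new_extent)
            elif d < 0:
                out = out._apply_pixel_op("flipud", new_extent)
            else:
                out = out.copy()
                out.extent = new_extent
        return out

    # -- general affine ----------------------------------------------------
    def affine(self, T: AffineTransform, resample: str = "bilinear") -> "ImageLayer":
        """Resample under an arbitrary invertible affine.

        The output grid is the axis-aligned bounding box of the transformed
        extent corners, at approximately the input pixel density; each
        output pixel is sampled at T^-1(center) with nearest or bilinear
        interpolation, and samples falling outside the source fill with 0.
        Lazy inputs are materialized first. Axis-aligned transforms take the
        exact permutation path instead (bit-preserving).
        """
        if T.is_axis_aligned:
            return self.apply_axis_aligned(T)
        if resample not in ("nearest", "bilinear"):
            raise ValueError("resample must be 'nearest' or 'bilinear'")
        img = self.materialize()
        e = img.extent
        corners = np.array(
            [[e.xmin, e.ymin], [e.xmin, e.ymax], [e.xmax, e.ymin], [e.xmax, e.ymax]]
        )
        tc = T(corners)
        new_extent = SpatialExtent(
            tc[:, 0].min(), tc[:, 1].min(), tc[:, 0].max(), tc[:, 1].max()
        )
        dx, dy = img.pixel_size
        # x-footprint of one transformed pixel sets the output pixel size
        out_dx = abs(T.M[0, 0]) * dx + abs(T.M[0, 1]) * dy
        out_dy = abs(T.M[1, 0]) * dx + abs(T.M[1, 1]) * dy
        ncols = max(1, int(round(new_extent.width / out_dx)))
        nrows = max(1, int(round(new_extent.height / out_dy)))
        xs = new_extent.xmin + (np.arange(ncols) + 0.5) * new_extent.width / ncols
        ys = new_extent.ymax - (np.arange(nrows) + 0.5) * new_extent.height / nrows
        gx, gy = np.meshgrid(xs, ys)
        src = T.inverse()(np.column_stack([gx.ravel(), gy.ravel()]))
        cols = (src[:, 0] - e.xmin) / dx - 0.5
        rows = (e.ymax - src[:, 1]) / dy - 0.5
        px = img.pixels.astype(float)
        if px.ndim == 2:
            px = px[:, :, None]
        out = np.zeros((nrows * ncols, px.shape[2]))
        if resample == "nearest":
            ri = np.rint(rows).astype(int)
            ci = np.rint(cols).astype(int)
            ok = (ri >= 0) & (ri < img.nrows) & (ci >= 0) & (ci < img.ncols)
            out[ok] = px[ri[ok], ci[ok]]
        else:
            r0 = np.floor(rows).astype(int)
            c0 = np.floor(cols).astype(int)
            fr = rows - r0
            fc = cols - c0
            for drow, dcol, w in (
                (0, 0, (1 - fr) * (1 - fc)),
                (0, 1, (1 - fr) * fc),
                (1, 0, fr * (1 - fc)),
                (1, 1, fr * fc),
            ):
                rr = r0 + drow
                cc = c0 + dcol
                ok = (rr >= 0) & (rr < img.nrows) & (cc >= 0) & (cc < img.ncols)
                out[ok] += w[ok, None] * px[rr[ok], cc[ok]]
        out = out.reshape(nrows, ncols, px.shape[2])
        if img.pixels.ndim == 2:
            out = out[:, :, 0]
        if resample == "nearest" and np.issubdtype(img.pixels.dtype, np.integer):
            out = out.astype(img.pixels.dtype)
        return ImageLayer(out, new_extent)

    # -- pixel extraction --------------------------------------------------
    def extract(self, geoms: GeometryLayer, fun: str = "mean") -> np.ndarray:
        """Summarize pixel values under each geometry.

        For polygons, ``fun`` runs over all pixels whose centers fall inside
        or on the polygon; for points, the containing pixel's value is
        returned. Geometries covering no pixel center (or outside the
        extent) yield NaN. Output is (n_geometries,) for grayscale images
        and (n_geometries, channels) otherwise.
        """
        if fun not in _EXTRACT_FUNS:
            raise ValueError(f"fun must be one of {sorted(_EXTRACT_FUNS)}")
        f = _EXTRACT_FUNS[fun]
        img = self.materialize()
        px = img.pixels.astype(float)
        gray = px.ndim == 2
        if gray:
            px = px[:, :, None]
        xs, ys = img.pixel_centers()
        n = len(geoms)
        out = np.full((n, px.shape[2]), np.nan)
        dx, dy = img.pixel_size
        e = img.extent
        for gi, geom in enumerate(geoms.geometry):
            if geom.is_empty:
                continue
            if geoms.family == "point":
                for pt in (
                    geom.geoms if geom.geom_type == "MultiPoint" else [geom]
                ):
                    c = int(np.floor((pt.x - e.xmin) / dx))
                    r = int(np.floor((e.ymax - pt.y) / dy))
                    if 0 <= r < img.nrows and 0 <= c < img.ncols:
                        out[gi] = px[r, c]
                        break
                continue
            xmin, ymin, xmax, ymax = shapely.bounds(geom)
            csel = np.nonzero((xs >= xmin - dx) & (xs <= xmax + dx))[0]
            rsel = np.nonzero((ys >= ymin - dy) & (ys <= ymax + dy))[0]
            if not len(csel) or not len(rsel):
                continue
            gx, gy = np.meshgrid(xs[csel], ys[rsel])
            inside = shapely.intersects_xy(geom, gx.ravel(), gy.ravel())
            if not inside.any():
                continue
            block = px[np.ix_(rsel, csel)].reshape(-1, px.shape[2])
            out[gi] = f(block[inside], axis=0)
        return out[:, 0] if gray else out

    # -- downsample / crop -------------------------------------------------
    def downsample(self, factor: int) -> "ImageLayer":
        """Block-mean downsampling by an integer factor; edge blocks are
        partial means. The extent is unchanged."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("factor must be a positive integer")
        if factor == 1:
            return self.copy()
        img = self.materialize()
        px = img.pixels.astype(float)
        gray = px.ndim == 2
        if gray:
            px = px[:, :, None]
        ridx = np.arange(0, img.nrows, factor)
        cidx = np.arange(0, img.ncols, factor)
        sums = np.add.reduceat(np.add.reduceat(px, ridx, axis=0), cidx, axis=1)
        rcount = np.diff(np.append(ridx, img.nrows))
        ccount = np.diff(np.append(cidx, img.ncols))
        counts = np.outer(rcount, ccount)[:, :, None]
        out = sums / counts
        if gray:
            out = out[:, :, 0]
        return ImageLayer(out, img.extent)

    def crop(self, extent: SpatialExtent) -> "ImageLayer":
        """Keep pixels whose centers fall inside ``extent`` (clipped to the
        image); the result's extent is the retained pixel footprint."""
        inter = self.extent.intersection(extent)
        if inter is None:
            raise ValueError("crop extent is disjoint from the image extent")
        img = self.materialize()
        xs, ys = img.pixel_centers()
        csel = np.nonzero((xs >= inter.xmin) & (xs <= inter.xmax))[0]
        rsel = np.nonzero((ys >= inter.ymin) & (ys <= inter.ymax))[0]
        if not len(csel) or not len(rsel):
            raise ValueError("crop extent contains no pixel centers")
        dx, dy = img.pixel_size
        c0, c1 = csel[0], csel[-1]
        r0, r1 = rsel[0], rsel[-1]
        e = img.extent
        new_extent = SpatialExtent(
            e.xmin + c0 * dx,
            e.ymax - (r1 + 1) * dy,
            e.xmin + (c1 + 1) * dx,
            e.ymax - r0 * dy,
        )
        return ImageLayer(img.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(), new_extent)

    def __repr__(self) -> str:
        kind = "lazy" if self.is_lazy else "in-memory"
        return (
            f"ImageLayer({kind}, {self.nrows}x{self.ncols}"
            f"x{self.n_channels}, extent={self.extent.as_tuple()})"
        )


def load_image(
    path: str, extent: SpatialExtent | None = None, lazy: bool = False
) -> ImageLayer:
    """Load a TIFF or PNG as an extent-registered image layer.

    When ``extent`` is omitted a sidecar ``<path>.extent.json`` holding
    ``{"xmin": ..., "ymin": ..., "xmax": ..., "ymax": ...}`` is consulted.
    With ``lazy=True`` only the header is read; pixel access is deferred to
    :meth:`ImageLayer.materialize`.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if extent is None:
        sidecar = path + ".extent.json"
        if not os.path.exists(sidecar):
            raise ValueError(
                f"no extent given and no sidecar file {sidecar!r}; an image "
                "cannot be registered without a spatial extent"
            )
        with open(sidecar) as fh:
            d = json.load(fh)
        extent = SpatialExtent(d["xmin"], d["ymin"], d["xmax"], d["ymax"])
    if lazy:
        return ImageLayer._lazy(path, extent)
    return ImageLayer(_read_pixels(path), extent)
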