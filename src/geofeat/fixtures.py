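"""Deterministic synthetic datasets for demos and tests.

Two generators: :func:`synth_dataset` builds a fully populated in-memory
container emulating an imaging-based experiment (cell centroids and
segmentation polygons, Poisson counts, per-gene transcript spots scattered
around the expressing cell, a tissue boundary, two annotation regions and a
smooth gradient image); :func:`synth_visium_dir` writes a complete
Visium-dialect Space Ranger output directory to disk.

Both are pure functions of their arguments: the same seed yields an
identical result, bit for bit. The statistical choices (independent
Poisson counts with per-gene means log-uniform in [0.1, 20], isotropic
Gaussian transcript scatter with sigma = 2% of the extent width) are
fixture conventions chosen to resemble desk-scale spatial data, not claims
about any real platform.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import shapely
from PIL import Image as PILImage
from scipy.spatial import Voronoi

from .container import SpatialFeatureContainer
from .geometry import GeometryLayer, SpatialExtent

__all__ = ["synth_dataset", "synth_visium_dir"]

GENE_MEAN_RANGE = (0.1, 20.0)  # log-uniform per-gene Poisson means
SCATTER_FRAC = 0.02  # transcript scatter sigma as a fraction of extent width


def _bounded_voronoi(xy: np.ndarray, extent: SpatialExtent) -> list[shapely.Polygon]:
    """Voronoi cells of ``xy`` clipped to the extent.

    Points are mirrored across all four extent edges so every original
    point's region is finite; regions are then intersected with the extent
    rectangle.
    """
    n = len(xy)
    mirrors = [
        np.column_stack([2 * extent.xmin - xy[:, 0], xy[:, 1]]),
        np.column_stack([2 * extent.xmax - xy[:, 0], xy[:, 1]]),
        np.column_stack([xy[:, 0], 2 * extent.ymin - xy[:, 1]]),
        np.column_stack([xy[:, 0], 2 * extent.ymax - xy[:, 1]]),
    ]
    vor = Voronoi(np.concatenate([xy] + mirrors))
    box = extent.as_polygon()
    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = shapely.Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        cells.append(poly.intersection(box))
    return cells


def synth_dataset(
    n_cells: int = 80,
    n_genes: int = 30,
    extent: SpatialExtent = SpatialExtent(0.0, 0.0, 1000.0, 800.0),
    seed: int = 0,
) -> SpatialFeatureContainer:
    """Generate a fully populated synthetic container.

    Contents: uniform cell centroids in ``extent`` ("centroids" column
    points), bounded Voronoi segmentation polygons ("cellSeg"), Poisson
    counts, per-gene transcript multipoints ("spots" row geometry, exactly
    matching the count matrix), a buffered convex-hull tissue boundary and
    two half-extent annotation regions named "left" and "right", plus a
    smooth diagonal-gradient grayscale image over the extent.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3 (Voronoi segmentation needs 3 points)")
    rng = np.random.default_rng(seed)
    xy = np.column_stack(
        [
            rng.uniform(extent.xmin, extent.xmax, n_cells),
            rng.uniform(extent.ymin, extent.ymax, n_cells),
        ]
    )
    lo, hi = np.log10(GENE_MEAN_RANGE[0]), np.log10(GENE_MEAN_RANGE[1])
    mu = 10.0 ** rng.uniform(lo, hi, n_genes)
    counts = rng.poisson(mu[:, None], size=(n_genes, n_cells))
    sigma = SCATTER_FRAC * extent.width
    spot_geoms = []
    for g in range(n_genes):
        pts = []
        for i in range(n_cells):
            k = counts[g, i]
            if k:
                pts.append(xy[i] + rng.normal(0.0, sigma, size=(k, 2)))
        if pts:
            spot_geoms.append(shapely.MultiPoint(np.concatenate(pts)))
        else:
            spot_geoms.append(shapely.MultiPoint())

    row_meta = pd.DataFrame(
        {
            "id": [f"gene_{g}" for g in range(n_genes)],
            "symbol": [f"Gene{g}" for g in range(n_genes)],
            "mean_count": mu,
        }
    )
    col_meta = pd.DataFrame(
        {
            "cell_id": [f"cell_{i}" for i in range(n_cells)],
            "sample_id": "synth",
        }
    )
    c = SpatialFeatureContainer(
        {"counts": sp.csr_matrix(counts)},
        row_meta=row_meta,
        col_meta=col_meta,
        units="micron",
    )
    c.set_geometry(
        "col", "centroids", GeometryLayer([shapely.Point(p) for p in xy])
    )
    cells = _bounded_voronoi(xy, extent)
    c.set_geometry(
        "col",
        "cellSeg",
        GeometryLayer(cells, pd.DataFrame({"area": [p.area for p in cells]})),
    )
    c.set_geometry("row", "spots", GeometryLayer(spot_geoms, validate=False))

    hull = shapely.convex_hull(shapely.MultiPoint(xy)).buffer(3 * sigma)
    c.set_geometry(
        "annot", "tissue", GeometryLayer([hull], pd.DataFrame({"name": ["tissue"]}))
    )
    xmid = 0.5 * (extent.xmin + extent.xmax)
    regions = [
        shapely.box(extent.xmin, extent.ymin, xmid, extent.ymax),
        shapely.box(xmid, extent.ymin, extent.xmax, extent.ymax),
    ]
    c.set_geometry(
        "annot",
        "regions",
        GeometryLayer(regions, pd.DataFrame({"name": ["left", "right"]})),
    )

    from .images import ImageLayer

    nrows, ncols = 64, 80
    xn = (np.arange(ncols) + 0.5) / ncols
    yn = (np.arange(nrows) + 0.5) / nrows
    gradient = 0.5 * (xn[None, :] + yn[:, None])  # smooth ramp in [0, 1]
    c.set_image("gradient", ImageLayer(gradient, extent))
    c.metadata["generator"] = {"n_cells": n_cells, "n_genes": n_genes, "seed": seed}
    return c


def synth_visium_dir(
    n_spots_row: int = 6,
    n_genes: int = 20,
    seed: int = 0,
    outdir: str | Path = ".",
) -> Path:
    """Write a complete synthetic Visium-dialect directory.

    Spots sit on a hexagonally packed array (row pitch = sqrt(3)/2 of the
    200 full-res-pixel column pitch) with ``spot_diameter_fullres = 100``.
    The low-res tissue image is a horizontal grayscale ramp whose value at
    full-resolution position x is ``255 * x / W`` (W = full-res frame
    width), written at a ``tissue_lowres_scalef`` that keeps the PNG at
    most 200 pixels wide. Counts are Poisson with log-uniform per-gene
    means. Returns the directory path.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    mat_dir = outdir / "filtered_feature_bc_matrix"
    spatial = outdir / "spatial"
    mat_dir.mkdir(parents=True, exist_ok=True)
    spatial.mkdir(parents=True, exist_ok=True)

    pitch = 200.0  # center-to-center distance within a row, full-res px
    spot_d = 100.0
    margin = 150.0
    rows = []
    for r in range(n_spots_row):
        for k in range(n_spots_row):
            array_col = 2 * k + (r % 2)
            x = margin + array_col * pitch / 2
            y = margin + r * pitch * np.sqrt(3) / 2
            rows.append((f"BC{r:02d}{k:02d}-1", 1, r, array_col, y, x))
    positions = pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "in_tissue",
            "array_row",
            "array_col",
            "pxl_row_in_fullres",
            "pxl_col_in_fullres",
        ],
    )
    W = positions["pxl_col_in_fullres"].max() + margin
    H = positions["pxl_row_in_fullres"].max() + margin
    scalef = min(1.0, 200.0 / W)
    w_low = max(1, int(round(W * scalef)))
    h_low = max(1, int(round(H * scalef)))
    # value at lowres column c equals the ramp at its full-res x center
    ramp = np.round(255.0 * (np.arange(w_low) + 0.5) / w_low).astype(np.uint8)
    img = np.tile(ramp, (h_low, 1))
    PILImage.fromarray(img, mode="L").save(spatial / "tissue_lowres_image.png")

    n_spots = len(positions)
    lo, hi = np.log10(GENE_MEAN_RANGE[0]), np.log10(GENE_MEAN_RANGE[1])
    mu = 10.0 ** rng.uniform(lo, hi, n_genes)
    X = sp.csr_matrix(rng.poisson(mu[:, None], size=(n_genes, n_spots)))
    sio.mmwrite(str(mat_dir / "matrix.mtx"), X.tocoo())
    with open(mat_dir / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(positions["barcode"]) + "\n")
    with open(mat_dir / "features.tsv", "w") as fh:
        for g in range(n_genes):
            fh.write(f"GENE{g:05d}\tSym{g}\tGene Expression\n")
    positions.to_csv(spatial / "tissue_positions.csv", index=False)
    scalefactors = {
        "spot_diameter_fullres": spot_d,
        "tissue_lowres_scalef": scalef,
        "tissue_hires_scalef": min(1.0, 2000.0 / W),
        "fiducial_diameter_fullres": 1.5 * spot_d,
    }
    (spatial / "scalefactors_json.json").write_text(json.dumps(scalefactors))
    return outdir
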