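"""Readers and on-disk serialization.

Covers three surfaces: (1) Space Ranger-style Visium output directories
(MatrixMarket counts + barcode/feature TSVs, ``tissue_positions.csv``,
``scalefactors_json.json``, low-resolution PNG), (2) transcript-spot CSV
tables reformatted to per-gene multipoints with a GeoParquet cache, and
(3) a language-agnostic directory layout for whole containers: MatrixMarket
assays, CSV metadata, GeoParquet geometry layers, JSON graphs, CSV local
results and lossless TIFF images, inventoried by a ``manifest.json``.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq
import scipy.io as sio
import scipy.sparse as sp
import shapely
import tifffile

from .container import SpatialFeatureContainer, new_container
from .geometry import GeometryLayer, SpatialExtent
from .graphs import SpatialGraph
from .images import ImageLayer

__all__ = [
    "read_visium_like",
    "read_transcript_spots",
    "write_geoparquet",
    "read_geoparquet",
    "save_container",
    "load_container",
]

logger = logging.getLogger(__name__)

SPOT_POLY_SEGMENTS = 32  # regular 32-gon approximation of the spot circle

_POSITIONS_HEADER = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


# ---------------------------------------------------------------------------
# GeoParquet
# ---------------------------------------------------------------------------

def write_geoparquet(layer: GeometryLayer, path: str | Path) -> None:
    """Write a geometry layer as GeoParquet (WKB geometry column plus the
    standard ``geo`` file metadata). Attribute columns are stored as
    ordinary Parquet columns."""
    wkb = [shapely.to_wkb(g) for g in layer.geometry]
    data = {col: layer.attributes[col] for col in layer.attributes.columns}
    table = pa.table({**data, "geometry": pa.array(wkb, type=pa.binary())})
    geom_types = sorted({g.geom_type for g in layer.geometry})
    geo_meta = {
        "version": "1.1.0",
        "primary_column": "geometry",
        "columns": {
            "geometry": {"encoding": "WKB", "geometry_types": geom_types}
        },
    }
    table = table.replace_schema_metadata(
        {b"geo": json.dumps(geo_meta).encode()}
    )
    pq.write_table(table, str(path))


def read_geoparquet(path: str | Path) -> GeometryLayer:
    """Read a GeoParquet file into a geometry layer; coordinates round-trip
    bit-exactly through WKB."""
    table = pq.read_table(str(path))
    meta = table.schema.metadata or {}
    if b"geo" not in meta:
        raise ValueError(f"{path}: not a GeoParquet file (no 'geo' metadata)")
    geo = json.loads(meta[b"geo"])
    geom_col = geo.get("primary_column", "geometry")
    if geom_col not in table.column_names:
        raise ValueError(f"{path}: geometry column {geom_col!r} missing")
    geoms = [shapely.from_wkb(b) for b in table.column(geom_col).to_pylist()]
    attrs = table.drop_columns([geom_col]).to_pandas()
    return GeometryLayer(geoms, attrs, validate=False)


# ---------------------------------------------------------------------------
# Transcript spots
# ---------------------------------------------------------------------------

def read_transcript_spots(
    path: str | Path,
    x_col: str = "x",
    y_col: str = "y",
    gene_col: str = "gene",
    cache: str | Path | None = None,
) -> dict[str, shapely.MultiPoint]:
    """Read a transcript-spot CSV into one multipoint per gene.

    Genes are grouped in order of first appearance and spot order is
    preserved within each gene. When ``cache`` is given, the result is
    written there as GeoParquet (columns ``gene``, ``geometry``); a later
    call finding a cache newer than the source CSV reads the cache instead
    of re-parsing the CSV.
    """
    path = Path(path)
    if cache is not None:
        cache = Path(cache)
        if cache.exists() and cache.stat().st_mtime >= path.stat().st_mtime:
            logger.info("reading transcript spots from cache %s", cache)
            layer = read_geoparquet(cache)
            return dict(zip(layer.attributes["gene"], layer.geometry))
    df = pd.read_csv(path)
    for col in (x_col, y_col, gene_col):
        if col not in df.columns:
            raise ValueError(f"{path}: column {col!r} not found in CSV header")
    for col in (x_col, y_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}: non-numeric {col!r} value {df[col].iloc[row]!r} "
                f"at data row {row}"
            )
        df[col] = vals
    out: dict[str, shapely.MultiPoint] = {}
    for gene, grp in df.groupby(gene_col, sort=False):
        out[str(gene)] = shapely.MultiPoint(grp[[x_col, y_col]].to_numpy())
    if cache is not None:
        layer = GeometryLayer(
            list(out.values()),
            pd.DataFrame({"gene": list(out.keys())}),
            validate=False,
        )
        write_geoparquet(layer, cache)
        logger.info("wrote transcript-spot cache %s", cache)
    return out


# ---------------------------------------------------------------------------
# Visium-dialect reader
# ---------------------------------------------------------------------------

def _open_maybe_gz(base: Path):
    for p in (base, base.with_name(base.name + ".gz")):
        if p.exists():
            return p
    raise FileNotFoundError(f"required file missing: {base} (or {base}.gz)")


def _read_tsv(path: Path, names) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None)
    df.columns = names[: df.shape[1]] + [
        f"col{i}" for i in range(len(names), df.shape[1])
    ]
    return df


def read_visium_like(directory: str | Path, y_convention: str = "up") -> SpatialFeatureContainer:
    """Read a Visium-style Space Ranger output directory.

    Builds a container in the full-resolution pixel frame with column
    geometries "centroids" (spot centers) and "spotPoly" (centers buffered
    to regular 32-gons of radius spot_diameter_fullres / 2), and the
    low-resolution tissue image registered so image and spots co-align.

    With the default ``y_convention="up"`` the Space Ranger pixel-row
    coordinate (which grows downward) is flipped to y-up using the
    full-resolution height inferred from the low-res image height and
    ``tissue_lowres_scalef``; with ``"down"`` raw pixel coordinates are
    kept and the stored image array is flipped instead, so the two layers
    still co-register under the container's top-row-at-ymax convention.
    """
    if y_convention not in ("up", "down"):
        raise ValueError("y_convention must be 'up' or 'down'")
    directory = Path(directory)
    mat_dir = directory / "filtered_feature_bc_matrix"
    mtx_path = _open_maybe_gz(mat_dir / "matrix.mtx")
    barcodes_path = _open_maybe_gz(mat_dir / "barcodes.tsv")
    features_path = _open_maybe_gz(mat_dir / "features.tsv")
    positions_path = directory / "spatial" / "tissue_positions.csv"
    if not positions_path.exists():
        legacy = directory / "spatial" / "tissue_positions_list.csv"
        if legacy.exists():
            raise ValueError(
                f"found legacy headerless {legacy}; this reader supports the "
                "Space Ranger >= 2.0 'tissue_positions.csv' dialect only — "
                "add the standard header and rename the file"
            )
        raise FileNotFoundError(f"required file missing: {positions_path}")
    scalef_path = directory / "spatial" / "scalefactors_json.json"
    if not scalef_path.exists():
        raise FileNotFoundError(f"required file missing: {scalef_path}")
    image_path = directory / "spatial" / "tissue_lowres_image.png"
    if not image_path.exists():
        raise FileNotFoundError(f"required file missing: {image_path}")

    X = sio.mmread(str(mtx_path)).tocsr()
    barcodes = _read_tsv(barcodes_path, ["barcode"])["barcode"].tolist()
    features = _read_tsv(features_path, ["feature_id", "symbol", "feature_type"])
    if X.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {X.shape} but features/barcodes have "
            f"{len(features)}/{len(barcodes)} rows"
        )
    positions = pd.read_csv(positions_path)
    missing = [h for h in _POSITIONS_HEADER if h not in positions.columns]
    if missing:
        raise ValueError(
            f"{positions_path}: missing expected columns {missing} "
            f"(Space Ranger >= 2.0 header required)"
        )
    pos_barcodes = set(positions["barcode"])
    mat_barcodes = set(barcodes)
    extra = pos_barcodes - mat_barcodes
    absent = mat_barcodes - pos_barcodes
    if extra or absent:
        raise ValueError(
            f"barcode mismatch between matrix and tissue_positions.csv: "
            f"{len(extra)} position barcode(s) absent from the matrix, "
            f"{len(absent)} matrix barcode(s) without positions"
        )
    positions = positions.set_index("barcode").loc[barcodes].reset_index()

    with open(scalef_path) as fh:
        scalef = json.load(fh)
    spot_d = float(scalef["spot_diameter_fullres"])
    lowres_scale = float(scalef["tissue_lowres_scalef"])
    from PIL import Image as PILImage

    px = np.asarray(PILImage.open(image_path))
    h_low, w_low = px.shape[0], px.shape[1]
    h_full = h_low / lowres_scale
    w_full = w_low / lowres_scale

    xs = positions["pxl_col_in_fullres"].to_numpy(dtype=float)
    ys_down = positions["pxl_row_in_fullres"].to_numpy(dtype=float)
    if y_convention == "up":
        ys = h_full - ys_down
        img_px = px
    else:
        ys = ys_down
        img_px = px[::-1].copy()

    col_meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": directory.name,
            "in_tissue": positions["in_tissue"].to_numpy(),
            "array_row": positions["array_row"].to_numpy(),
            "array_col": positions["array_col"].to_numpy(),
        }
    )
    row_meta = features.rename(columns={"feature_id": "id"})
    c = SpatialFeatureContainer(
        {"counts": X}, row_meta=row_meta, col_meta=col_meta, units="full_res_pixel"
    )
    centroids = GeometryLayer(
        [shapely.Point(x, y) for x, y in zip(xs, ys)], validate=False
    )
    c.set_geometry("col", "centroids", centroids)
    quad_segs = SPOT_POLY_SEGMENTS // 4
    spot_poly = GeometryLayer(
        [g.buffer(spot_d / 2, quad_segs=quad_segs) for g in centroids.geometry],
        validate=False,
    )
    c.set_geometry("col", "spotPoly", spot_poly)
    c.set_image(
        "lowres", ImageLayer(img_px, SpatialExtent(0.0, 0.0, w_full, h_full))
    )
    c.metadata["scalefactors"] = scalef
    return c


# ---------------------------------------------------------------------------
# Whole-container serialization
# ---------------------------------------------------------------------------

def _write_matrix(m, path: Path) -> str:
    if sp.issparse(m):
        sio.mmwrite(str(path), m.tocoo())
        return "sparse"
    sio.mmwrite(str(path), np.asarray(m))
    return "dense"


def _dtypes_of(df: pd.DataFrame) -> dict[str, str]:
    return {col: str(dt) for col, dt in df.dtypes.items()}


def _read_meta_csv(path: Path, columns: list[str], dtypes: dict[str, str], n: int) -> pd.DataFrame:
    if not columns:
        return pd.DataFrame(index=pd.RangeIndex(n))
    df = pd.read_csv(path)
    for col, dt in dtypes.items():
        if df[col].isna().all() and not dt.startswith("float"):
            # all-missing columns lose their dtype through CSV; leave as-is
            continue
        df[col] = df[col].astype(dt)
    return df[columns]


def save_container(c: SpatialFeatureContainer, directory: str | Path) -> None:
    """Serialize a container to a directory of open formats.

    Layout: ``manifest.json`` (format version, units, inventory, image
    extents, metadata-table dtypes), ``assays/<name>.mtx``,
    ``row_meta.csv`` / ``col_meta.csv``, GeoParquet geometry layers under
    ``geometries/{col,row,annot}/``, JSON graphs under
    ``graphs/{col,annot}/``, per-feature CSVs under
    ``local_results/<statistic>/`` and lossless TIFF images under
    ``images/``. Lazy images are materialized on save.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "format_version": c.FORMAT_VERSION,
        "units": c.units,
        "shape": [c.n_features, c.n_locations],
        "metadata": c.metadata,
        "assays": {},
        "geometries": {"col": [], "row": [], "annot": []},
        "graphs": {"col": [], "annot": []},
        "local_results": {},
        "images": {},
        "row_meta": {
            "columns": list(c.row_meta.columns),
            "dtypes": _dtypes_of(c.row_meta),
        },
        "col_meta": {
            "columns": list(c.col_meta.columns),
            "dtypes": _dtypes_of(c.col_meta),
        },
    }
    (directory / "assays").mkdir(exist_ok=True)
    for name, m in c.assays.items():
        manifest["assays"][name] = {
            "file": f"assays/{name}.mtx",
            "storage": _write_matrix(m, directory / "assays" / f"{name}.mtx"),
        }
    c.row_meta.to_csv(directory / "row_meta.csv", index=False)
    c.col_meta.to_csv(directory / "col_meta.csv", index=False)
    for axis, gm in (
        ("col", c.col_geometries),
        ("row", c.row_geometries),
        ("annot", c.annot_geometries),
    ):
        if gm:
            (directory / "geometries" / axis).mkdir(parents=True, exist_ok=True)
        for name, layer in gm.items():
            write_geoparquet(layer, directory / "geometries" / axis / f"{name}.parquet")
            manifest["geometries"][axis].append(name)
    for scope, gm in (("col", c.col_graphs), ("annot", c.annot_graphs)):
        if gm:
            (directory / "graphs" / scope).mkdir(parents=True, exist_ok=True)
        for name, g in gm.items():
            (directory / "graphs" / scope / f"{name}.json").write_text(g.to_json())
            manifest["graphs"][scope].append(name)
    for stat, per_feat in c.local_results.items():
        stat_dir = directory / "local_results" / stat
        stat_dir.mkdir(parents=True, exist_ok=True)
        files = {}
        for k, (feat, df) in enumerate(per_feat.items()):
            fname = f"{k}.csv"
            df.to_csv(stat_dir / fname, index=False)
            files[feat] = fname
        manifest["local_results"][stat] = files
    if c.images:
        (directory / "images").mkdir(exist_ok=True)
    for name, img in c.images.items():
        mat = img.materialize()
        tifffile.imwrite(directory / "images" / f"{name}.tiff", mat.pixels)
        manifest["images"][name] = {
            "file": f"images/{name}.tiff",
            "extent": list(mat.extent.as_tuple()),
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_container(directory: str | Path) -> SpatialFeatureContainer:
    """Load a container serialized by :func:`save_container`.

    Errors if the manifest's format version differs from this package's,
    or if any file the manifest declares is missing.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != SpatialFeatureContainer.FORMAT_VERSION:
        raise ValueError(
            f"container format version {version!r} does not match this "
            f"package's version {SpatialFeatureContainer.FORMAT_VERSION!r}"
        )

    def _need(rel: str) -> Path:
        p = directory / rel
        if not p.exists():
            raise FileNotFoundError(
                f"manifest declares {rel!r} but the file is missing"
            )
        return p

    n_features, n_locations = manifest["shape"]
    assays = {}
    for name, info in manifest["assays"].items():
        m = sio.mmread(str(_need(info["file"])))
        assays[name] = m.tocsr() if info["storage"] == "sparse" else np.asarray(m)
    row_meta = _read_meta_csv(
        _need("row_meta.csv"),
        manifest["row_meta"]["columns"],
        manifest["row_meta"]["dtypes"],
        n_features,
    )
    col_meta = _read_meta_csv(
        _need("col_meta.csv"),
        manifest["col_meta"]["columns"],
        manifest["col_meta"]["dtypes"],
        n_locations,
    )
    c = SpatialFeatureContainer(
        assays, row_meta=row_meta, col_meta=col_meta, units=manifest["units"]
    )
    c.metadata = manifest.get("metadata", {})
    for axis in ("col", "row", "annot"):
        for name in manifest["geometries"][axis]:
            layer = read_geoparquet(_need(f"geometries/{axis}/{name}.parquet"))
            c.set_geometry(axis, name, layer)
    for scope in ("col", "annot"):
        for name in manifest["graphs"][scope]:
            g = SpatialGraph.from_json(_need(f"graphs/{scope}/{name}.json").read_text())
            c.set_graph(scope, name, g)
    for stat, files in manifest["local_results"].items():
        for feat, fname in files.items():
            df = pd.read_csv(_need(f"local_results/{stat}/{fname}"))
            c.set_local_result(stat, feat, df)
    for name, info in manifest["images"].items():
        px = tifffile.imread(str(_need(info["file"])))
        c.set_image(name, ImageLayer(px, SpatialExtent(*info["extent"])))
    return c
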