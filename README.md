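# geofeat

A geospatially informed data container for spatial -omics, with the spatial
operations that make it useful.

Spatial transcriptomics assays — sequencing-based platforms with fixed
capture spots (Visium-style) and imaging-based platforms yielding
per-transcript coordinates and cell segmentations (Xenium/MERFISH-style) —
produce a gene-count matrix *plus* layers of spatial data: spot or cell
geometries, transcript point clouds, pathologist annotations, tissue
boundaries, and histology images. `geofeat` treats such a dataset the way a
GIS treats a map: one `SpatialFeatureContainer` holds the
`n_features x n_locations` count matrix together with

- **column geometries** (one simple-features geometry per matrix column:
  spot centroids, spot polygons, cell segmentations),
- **row geometries** (one per matrix row, e.g. per-gene transcript
  multipoints),
- **annotation geometries** (tissue boundaries, histological regions —
  not tied to matrix dimensions),
- **spatial neighborhood graphs** over columns or annotations (k nearest
  neighbors, distance bands, Delaunay triangulation with Gabriel pruning,
  queen contiguity) for downstream spatial statistics,
- **local results** — per-location statistics (e.g. local Moran's I per
  gene) stored as `(statistic, feature) -> n_locations x k` tables,
- **images** registered to the coordinate frame by a spatial extent,
  in-memory or lazy (header-only, with queued axis operations).

Everything shares one y-up Cartesian frame, so operations act on the whole
stack coherently: matrix subsetting filters the aligned geometry layers,
local results and graphs in lock-step; an affine transform
`p' = M p + v` moves every geometry and image together; cropping,
predicate joins (`intersects`, `contains`, `within`, `touches`),
annotation summaries, region splitting, and aggregation of cells or
transcript spots into new count matrices (square or hexagonal grids, or
arbitrary polygons) are all geometry-aware. Containers serialize to a
directory of open formats — MatrixMarket, CSV, JSON, GeoParquet and
lossless TIFF — readable from any language.

## Worked example

```python
import numpy as np
import geofeat as gf

# a fully populated synthetic dataset: 80 cells, 20 genes, Voronoi
# segmentation, per-gene transcript spots, annotations, gradient image
c = gf.synth_dataset(n_cells=80, n_genes=20, seed=1)
print(c.shape)                     # (20, 80)
print(int(c.assay().sum()))        # 7345 transcripts in the count matrix

# spatial neighborhood graph on cell centroids, row-standardized
gf.find_spatial_graph(c, "col", "centroids", "knn", {"k": 4}, "knn",
                      style="row_standardized")
W = c.get_graph("col", "knn").weight_matrix()
print(W.shape, float(W.sum(axis=1).max()))   # (80, 80) 1.0

# bin the transcript spots into hexagons -> a new count matrix
grid = gf.make_grid(c.bbox(), gf.GridSpec("hex", 140))
binned = gf.aggregate_transcripts(c, grid)
print(binned.shape, int(binned.assay().sum()))  # (20, 63) 7345  — conserved

# crop to the left annotation region; every aligned layer follows
left = c.get_geometry("annot", "regions").geometry[0]
sub = gf.crop(c, left, colgeom="centroids")
print(sub.n_locations, len(sub.get_geometry("col", "cellSeg")))  # 34 34
```

(The printed numbers are for seed 1; hexagon counts depend on the data
bounding box.) A thin CLI wraps the same library:
`geofeat convert visium <dir> -o <out>`, `geofeat crop`,
`geofeat transform`, `geofeat aggregate`, `geofeat spots2parquet`,
`geofeat fixtures ...`.

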