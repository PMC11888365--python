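# Methods

## The data model

A `SpatialFeatureContainer` is a feature-by-location count matrix with
spatial structure attached on three axes. Column geometry layers are
parallel to matrix columns (row *i* of the layer describes column *i* of
the matrix); row geometry layers are parallel to matrix rows (typically one
multipoint of transcript coordinates per gene); annotation layers are free
tables of geometries describing the tissue rather than the matrix.
Neighborhood graphs attach to the column axis or to a named annotation
layer, per-location statistic tables ("local results") attach to columns
under a two-level key `(statistic, feature)`, and raster images are placed
in the frame by an extent. Global per-gene statistics are ordinary columns
of the feature metadata table; only location-resolved results need the
dedicated store.

All coordinates live in a single 2-D Cartesian frame, y up, with one unit
system per container (a free string, e.g. `"full_res_pixel"` or
`"micron"`). Pixel registration follows the geospatial raster convention:
image row 0 is the top row, so column *c* has center
`x = xmin + (c + 0.5)·w/ncols` and row *r* has center
`y = ymax − (r + 0.5)·h/nrows`. Sources whose pixel rows grow downward
(e.g. Space Ranger spot coordinates) are flipped on read; readers that keep
the raw downward coordinates instead flip the stored pixel array so the
stack still co-registers.

### Synchronized subsetting

Selecting rows and/or columns filters every aligned structure in one step:
assays, metadata, column/row geometry layers, and every local-results
table. Column graphs are *filtered*, not recomputed: surviving nodes are
relabeled, only edges between survivors are kept, and the graph's metadata
gains `subsetted: true` so downstream code can decide whether a filtered
kNN graph is still meaningful. Row-standardized weights renormalize over
the surviving neighbors (weights are materialized from the stored binary
adjacency on demand, so renormalization is automatic). Annotation layers,
annotation graphs and images pass through unchanged. Duplicate indices are
rejected rather than replicated, because replication semantics for
geometries and graphs are ill-defined.

## Geometry and transforms

Geometry layers are homogeneous simple-features columns (point-like,
line-like or polygon-like; single and multi variants of one family may
mix, since clipping a polygon can produce a multipolygon). Validation
checks coordinate finiteness and polygon ring validity.

Affine maps are stored as `p' = M p + v` with `det M ≠ 0`. Named
constructors cover mirror (left-right and up-down), transpose
(`(x, y) → (y, x)`), translation, uniform scaling and rotation (degrees,
counter-clockwise); all pivoting kinds default to the container's
bounding-box center so a "canonical orientation" change does not move the
data away from its footprint. Rotation matrices snap entries below 1e-15
to zero so quarter-turn rotations are recognized as exact axis-aligned
maps.

Applying a transform to a container maps every geometry coordinate and
every image with the same function. Axis-aligned transforms (diagonal or
anti-diagonal `M`) move images exactly — a pixel permutation
(flips/anti-transpose) plus a recomputed extent — and therefore commute
bit-exactly with lazy evaluation; general affines resample (below).

## Images

Two flavors share one class: in-memory arrays, and lazy file references
(TIFF/PNG) that answer width/height/extent queries from the header alone.
Axis-aligned operations on lazy images append a pure pixel permutation to
a queue and update the extent immediately; `materialize()` loads the file
once and replays the queue, which is bit-identical to the eager path. This
reproduces a metadata-only handling contract for images too large to load
for every operation, without implementing chunked processing.

General affines resample by inverse mapping: the output grid is the
axis-aligned bounding box of the transformed extent corners at
approximately the input pixel density (one transformed-pixel footprint per
output pixel), each output center is pulled back through `T⁻¹` and sampled
with nearest or bilinear (default) interpolation, and samples outside the
source fill with zero. Pixel extraction under geometries uses pixel-*center*
containment (a pixel belongs to a polygon iff its center does, boundary
inclusive) — exact and cheap to verify against a brute-force loop, at the
cost of ignoring partial pixel coverage; geometries covering no pixel
center yield NaN. Downsampling is block means with partial edge blocks, so
the mean is preserved exactly when the factor divides the dimensions.

## Graphs

Four constructors share one uniform entry point
(`find_spatial_graph(container, scope, layer, method, params, name,
style)`):

- **kNN** — Euclidean, exact-distance ties broken toward the lower index
  (stable argsort over the full distance matrix, appropriate at the
  supported scales); the directed sets are symmetrized by union (an edge if
  either point selects the other), with a "mutual" option.
- **distance band** — edge iff distance ≤ `d_max`, inclusive; isolated
  nodes allowed.
- **Delaunay / Gabriel** — triangulation edges from scipy's Delaunay;
  Gabriel pruning keeps edge (i, j) iff the *open* disk with diameter ij
  contains no third point, so points exactly on the circle do not remove
  an edge. Collinear inputs are rejected with a clear message.
- **queen contiguity** — polygons sharing at least one boundary point,
  detected within a 1e-9 snap tolerance (`dwithin`); rook-style is a
  deliberate non-feature.

Graphs store each undirected pair once with a binary base weight; the
effective weight matrix applies the style on demand (row standardization
divides each non-isolated row by its degree, summing to 1 ± 1e-9).
Distances are metadata, not weights. Computing spatial statistics from the
graphs is out of scope; the container only builds, stores, filters and
serializes them (JSON: `{n_nodes, edges: [[i, j, w]...], style,
method_meta}`).

## Aggregation

Binning uses an *assignment point* per cell — the centroid of the chosen
column geometry (a polygonal segmentation reduces to its centroid; any
point layer can be supplied instead). Each point maps to at most one bin:
candidate bins are scanned in descending index with later assignments
overwritten, so a point on a shared boundary deterministically lands in
the lowest intersecting bin index and touching bins never double-count.
Consequently sum-aggregation conserves per-gene totals exactly (integer
arithmetic) whenever the bins cover all assignment points. Arbitrary
Python summary functions are supported; `sum` takes a sparse
matrix-product fast path. Transcript binning applies the same assignment
to every coordinate of the per-gene multipoints, yielding a new sparse
count matrix aligned to the original features (empty multipoints give
zero rows). Cells falling outside all bins are dropped and counted in the
output's `metadata["n_cells_outside"]`.

Square grids are axis-aligned tilings anchored at the extent's lower-left
corner (or an explicit origin), sized by the ceiling rule so boundary
cells may overhang. Hexagonal grids are flat-topped with column pitch
equal to `cellsize` (circumradius `cellsize/1.5`), vertical pitch
`√3 · R`, odd columns offset by half a pitch; the convention is fixed and
the *coverage* and interior-disjointness properties are what the tests
assert. Weighted or area-proportional splitting of a cell's counts across
bins is out of scope.

## IO

- **GeoParquet**: geometry as a WKB column plus the standard `geo` schema
  metadata (version 1.1.0), written and read with pyarrow directly; WKB
  preserves coordinates bit-exactly.
- **Transcript-spot CSVs** are grouped into one multipoint per gene and
  optionally cached as GeoParquet; a cache newer than its source CSV is
  read instead of the CSV.
- **Visium dialect**: pinned to the Space Ranger ≥ 2.0
  `tissue_positions.csv` header; the legacy headerless
  `tissue_positions_list.csv` is detected and rejected with a pointed
  message. Spot centers come from the full-resolution pixel columns; spot
  polygons are the centers buffered to regular 32-gons of radius
  `spot_diameter_fullres/2` (inscribed-polygon area deficit
  `1 − (n/2π)·sin(2π/n) ≈ 0.64%`). The full-resolution frame height is
  inferred as `lowres_height / tissue_lowres_scalef`, which both flips the
  spot y-coordinates to y-up and registers the low-res image extent so
  image and spots co-align. The positions table and the matrix barcodes
  must match as sets; mismatches error with counts in each direction.
- **Container serialization** is a directory inventoried by
  `manifest.json` (format version, units, dtypes of the metadata tables,
  image extents): MatrixMarket assays, CSV metadata and local results,
  GeoParquet geometries, JSON graphs, lossless TIFF images. Load verifies
  the format version and errors naming any declared-but-missing file.
  Lazy images are materialized on save. Metadata tables round-trip by
  restoring the recorded dtypes after CSV re-parsing; exotic dtypes
  (nested objects) are outside the guarantee.

## Synthetic data

`synth_dataset` emulates a small imaging-based experiment: uniform cell
centroids in the extent; segmentation polygons as Voronoi cells bounded by
mirroring the points across the extent edges and clipping; counts
independent Poisson with per-gene means log-uniform in [0.1, 20]
(spanning near-silent to highly expressed genes at desk scale); per-gene
transcript multipoints scattering each cell's count as isotropic Gaussian
offsets (σ = 2% of the extent width) around the centroid, so transcript
totals match the matrix by construction; a buffered convex-hull tissue
boundary; two half-extent annotation regions; and a smooth diagonal
gradient image. `synth_visium_dir` writes a complete Visium-dialect
directory: hexagonally packed spots at 200 full-res-pixel column pitch
with 100-pixel spot diameter, Poisson counts, and a horizontal-ramp
low-res PNG (≤ 200 px wide) whose value at full-res position x is
`255·x/W` — an analytically known image for verifying reader
co-registration. Both generators are pure functions of their arguments.

What the generators do *not* emulate: spatially structured expression
(domains, gradients of biology rather than intensity), segmentation
errors, doublets, platform noise beyond Poisson, multi-sample structure,
or realistic image content. Passing tests therefore demonstrate the
correctness of the container's bookkeeping and geometry/raster operations,
not robustness to the artifacts of real data.

## Numerical choices and limitations

- Default problem sizes in tests and the acceptance script (tens of cells
  and genes, hundreds of points, ≤ 200 geometries per oracle comparison)
  keep brute-force oracles exact and fast; all operations are O(n·m) safe
  at this scale, with STRtree indexing where it helps.
- Contiguity snap tolerance 1e-9 coordinate units; Gabriel disk test uses
  exact open-disk comparison; graph edge sets are compared as sets so
  cocircular Delaunay tie-breaking by the underlying triangulation is
  immaterial.
- Affine inverse round trips hold to ~1e-13 at the tested coordinate
  magnitudes (well inside the 1e-6 contract); image resampling error under
  a generic rotation is ≈ 0.2% of dynamic range for interior polygons
  ≥ 10 × 10 pixels.
- Out-of-scope by design: computing spatial statistics (the graphs' and
  local-results store's consumers), estimating registration transforms
  (transforms are user-supplied and applied), out-of-memory matrices,
  chunked image processing, OME-XML metadata, multi-sample concatenation,
  and vendor dialects beyond Visium-like directories and generic
  transcript CSVs.
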