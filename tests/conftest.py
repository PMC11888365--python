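import numpy as np
import pandas as pd
import pytest
import shapely

import geofeat as gf


@pytest.fixture
def small_container():
    """Fully populated synthetic container at desk scale."""
    return gf.synth_dataset(n_cells=30, n_genes=8, seed=11)


@pytest.fixture
def container_with_results(small_container):
    c = small_container
    rng = np.random.default_rng(5)
    for feat in ("Gene0", "Gene1"):
        c.set_local_result(
            "localmoran",
            feat,
            pd.DataFrame(
                {
                    "stat": rng.normal(size=c.n_locations),
                    "p_value": rng.uniform(size=c.n_locations),
                }
            ),
        )
    gf.find_spatial_graph(c, "col", "centroids", "knn", {"k": 3}, "knn")
    gf.find_spatial_graph(
        c, "col", "centroids", "delaunay", {"prune": "gabriel"}, "gabriel"
    )
    return c


def random_polygon_layer(n, rng, extent=(0.0, 0.0, 100.0, 100.0), size=8.0):
    """n random convex polygons (buffered random triangles) in the extent."""
    xmin, ymin, xmax, ymax = extent
    geoms = []
    for _ in range(n):
        cx = rng.uniform(xmin + size, xmax - size)
        cy = rng.uniform(ymin + size, ymax - size)
        pts = np.column_stack(
            [cx + rng.uniform(-size, size, 3), cy + rng.uniform(-size, size, 3)]
        )
        geoms.append(shapely.convex_hull(shapely.MultiPoint(pts)).buffer(1.0))
    return gf.GeometryLayer(geoms, pd.DataFrame({"value": rng.uniform(1, 10, n)}))


def random_point_layer(n, rng, extent=(0.0, 0.0, 100.0, 100.0)):
    xmin, ymin, xmax, ymax = extent
    xy = np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
    )
    return gf.GeometryLayer([shapely.Point(p) for p in xy]), xy
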