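import numpy as np
import pytest
import shapely

import urbanfuse as uf


@pytest.fixture(scope="session")
def registry():
    return uf.default_registry()


@pytest.fixture(scope="session")
def cfg():
    return uf.FusionConfig()


@pytest.fixture(scope="session")
def small_scene(cfg):
    """One modest synthetic city shared by read-only tests."""
    return uf.generate_city(uf.CityRecipe(n_rows=60, n_cols=60, seed=7), cfg)


def brute_force_assign(layer, grid, priority, sentinel=0):
    """Exhaustive per-cell maximum-area oracle for transport rasterization.

    Intersects every cell square with every per-class dissolved geometry;
    iterating classes in priority order with a strict '>' makes the earlier
    class win exact ties.
    """
    unions = uf.dissolve_by_class(layer)
    out = np.full(grid.shape, sentinel, dtype=int)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            cell = shapely.box(*grid.cell_bounds(r, c))
            best_code, best_area = sentinel, 0.0
            for code in priority:
                if code not in unions:
                    continue
                a = cell.intersection(unions[code]).area
                if a > best_area:
                    best_area, best_code = a, code
            out[r, c] = best_code
    return out


def random_transport_scene(rng, grid, n_polygons, codes=(1, 2, 3)):
    """Random polygonal transport layer within (and slightly beyond) a grid."""
    w = grid.n_cols * grid.cell_size
    h = grid.n_rows * grid.cell_size
    geoms, cc = [], []
    for _ in range(n_polygons):
        kind = rng.integers(3)
        x = grid.origin_x + rng.uniform(-0.1, 1.1) * w
        y = grid.origin_y - rng.uniform(-0.1, 1.1) * h
        if kind == 0:  # box
            geoms.append(shapely.box(x, y - rng.uniform(5, h / 2),
                                     x + rng.uniform(5, w / 2), y))
        elif kind == 1:  # triangle
            pts = [(x + rng.uniform(-w / 3, w / 3), y + rng.uniform(-h / 3, h / 3))
                   for _ in range(3)]
            tri = shapely.Polygon(pts)
            if tri.area == 0:
                tri = shapely.box(x, y - 10, x + 10, y)
            geoms.append(tri)
        else:  # buffered segment (road-like)
            x2 = x + rng.uniform(-w / 2, w / 2)
            y2 = y + rng.uniform(-h / 2, h / 2)
            geoms.append(shapely.LineString([(x, y), (x2, y2)])
                         .buffer(rng.uniform(2, 12)))
        cc.append(int(rng.choice(codes)))
    return uf.TransportLayer(geoms, cc, grid.crs_id)
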