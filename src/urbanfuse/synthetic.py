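"""Synthetic-city generator: aligned fixture layers for the whole pipeline.

Real Copernicus products cannot ship with a test suite, so this module
fabricates a small city with the same statistical structure: a 10 m base
land-cover raster (grassland matrix, parks, crops, shrubs, a meandering river
and a lake), a water-and-wetness status raster with permanent-wet fringes, a
building-height layer (log-normal heights on city blocks, clipped to the
2-368 m span of the height product), and a centreline road/rail network with
per-class codes.  Every draw comes from one seeded generator, so a recipe is
byte-reproducible.

The generator also returns the *expected* fused map, computed by a
deliberately naive per-pixel loop over :func:`urbanfuse.fusion.fuse_pixel`,
independent of the vectorised fusion path — the oracle for the end-to-end
equivalence tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .classes import FusionConfig
from .errors import GridError
from .fusion import PixelState, fuse_pixel, height_to_class
from .grid import NODATA, CategoricalRaster, ContinuousRaster, GridSpec
from .io import TransportLayer, ValidationPoints
from .accuracy import ConfusionMatrix

# raw product codes used by the generator (match the default code tables)
RAW_SEALED, RAW_NEEDLE, RAW_BROADLEAF = 1, 2, 3
RAW_SHRUB, RAW_GRASS, RAW_CROP, RAW_BARE, RAW_WATER = 5, 6, 7, 9, 10
WET_PERMANENT_WATER, WET_PERMANENT_WETNESS = 1, 3
T_FAST, T_OTHER, T_RAIL = 1, 2, 3


@dataclass
class CityRecipe:
    """Everything that shapes a synthetic city; the seed fixes every draw."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 10.0
    crs_id: int = 3035
    origin_x: float = 4_468_000.0
    origin_y: float = 2_812_000.0
    seed: int = 0
    # built structure
    block_density: float = 0.5       # probability a city block is built up
    building_fill: float = 0.6       # fraction of a built block carrying a height
    height_log_mean: float = math.log(8.0)   # log-normal, median 8 m
    height_log_sigma: float = 0.6
    height_range: tuple[float, float] = (2.0, 368.0)
    sub_floor_fraction: float = 0.03  # sealed cells given a sub-2 m height
    # transport
    road_spacing: int = 25           # cells between gridded road centrelines
    fast_transit: bool = True
    railway: bool = True
    # water and vegetation
    river: bool = True
    river_width: int = 3
    lake: bool = True
    park_patches: int = 6
    crop_patches: int = 5
    shrub_fraction: float = 0.03
    bare_fraction: float = 0.02
    wet_fringe_prob: float = 0.8
    nodata_margin: int = 2           # rows of base nodata along the top edge

    def __post_init__(self) -> None:
        for name in ("block_density", "building_fill", "sub_floor_fraction",
                     "shrub_fraction", "bare_fraction", "wet_fringe_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GridError(f"{name} must be in [0, 1], got {v}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("recipe grid must be at least 1x1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.crs_id, self.origin_x, self.origin_y,
                        self.cell_size, self.n_rows, self.n_cols)


@dataclass
class CityScene:
    """The four aligned layers plus ground truth for one generated city."""

    grid: GridSpec
    base: CategoricalRaster            # raw base product codes
    wetness: CategoricalRaster         # raw wetness status codes
    heights_m: ContinuousRaster        # metric heights, NaN = no building
    heights_class: CategoricalRaster   # pre-binned classes 0..10 (0 = none)
    transport_vector: TransportLayer   # centrelines with raw transport codes
    transport_raster: CategoricalRaster  # rasterized transport, 0 = none
    expected: CategoricalRaster        # oracle fused map
    true_counts: dict[int, int] = field(default_factory=dict)


def _rand_rect(rng, n_rows, n_cols, max_h, max_w):
    h = int(rng.integers(3, max(4, max_h)))
    w = int(rng.integers(3, max(4, max_w)))
    r = int(rng.integers(0, max(1, n_rows - h)))
    c = int(rng.integers(0, max(1, n_cols - w)))
    return r, c, h, w


def _paint_base(recipe: CityRecipe, rng) -> np.ndarray:
    R, C = recipe.n_rows, recipe.n_cols
    base = np.full((R, C), RAW_GRASS, dtype=np.uint8)
    # crops towards the fringes
    for _ in range(recipe.crop_patches):
        r, c, h, w = _rand_rect(rng, R, C, R // 4, C // 4)
        if min(r, c, R - r - h, C - c - w) < max(R, C) // 5:
            base[r:r + h, c:c + w] = RAW_CROP
    # parks: broadleaved and needle-leaved stands
    for i in range(recipe.park_patches):
        r, c, h, w = _rand_rect(rng, R, C, R // 6, C // 6)
        base[r:r + h, c:c + w] = RAW_BROADLEAF if i % 2 == 0 else RAW_NEEDLE
    # scattered shrubs and bare ground
    specks = rng.random((R, C))
    base[specks < recipe.shrub_fraction] = RAW_SHRUB
    bare = (specks >= recipe.shrub_fraction) & (specks < recipe.shrub_fraction
                                                + recipe.bare_fraction)
    base[bare] = RAW_BARE
    return base


def _paint_water(recipe: CityRecipe, rng, base: np.ndarray) -> np.ndarray:
    R, C = base.shape
    water = np.zeros_like(base, dtype=bool)
    if recipe.river and C >= 8:
        amp = C / 12
        centre = C * 0.7
        for r in range(R):
            c0 = int(centre + amp * math.sin(2 * math.pi * r / max(R, 1) * 2)
                     + rng.normal(0, 0.3))
            lo = max(0, c0 - recipe.river_width // 2)
            hi = min(C, lo + recipe.river_width)
            water[r, lo:hi] = True
    if recipe.lake and min(R, C) >= 20:
        cr, cc = int(R * 0.25), int(C * 0.25)
        rad = min(R, C) // 15
        rr, cc2 = np.ogrid[:R, :C]
        water |= (rr - cr) ** 2 + (cc2 - cc) ** 2 <= rad ** 2
    base[water] = RAW_WATER
    return water


def _paint_wetness(recipe: CityRecipe, rng, water: np.ndarray) -> np.ndarray:
    R, C = water.shape
    wetness = np.zeros((R, C), dtype=np.uint8)
    # permanent water on part of the water body itself
    wetness[water & (rng.random(water.shape) < 0.25)] = WET_PERMANENT_WATER
    # wet fringe: land cells bordering water
    fringe = np.zeros_like(water)
    fringe[1:, :] |= water[:-1, :]
    fringe[:-1, :] |= water[1:, :]
    fringe[:, 1:] |= water[:, :-1]
    fringe[:, :-1] |= water[:, 1:]
    fringe &= ~water
    pick = fringe & (rng.random(water.shape) < recipe.wet_fringe_prob)
    wetness[pick] = WET_PERMANENT_WETNESS
    return wetness


def _road_network(recipe: CityRecipe, grid: GridSpec) -> TransportLayer:
    geoms, codes = [], []
    if recipe.road_spacing <= 0:
        return TransportLayer(geoms, codes, grid.crs_id)
    s = grid.cell_size
    x0, y0 = grid.origin_x, grid.origin_y
    width_m, height_m = grid.n_cols * s, grid.n_rows * s
    for c in range(recipe.road_spacing, grid.n_cols, recipe.road_spacing):
        x = x0 + (c + 0.5) * s
        geoms.append(LineString([(x, y0), (x, y0 - height_m)]))
        codes.append(T_OTHER)
    for r in range(recipe.road_spacing, grid.n_rows, recipe.road_spacing):
        y = y0 - (r + 0.5) * s
        geoms.append(LineString([(x0, y), (x0 + width_m, y)]))
        codes.append(T_OTHER)
    if recipe.fast_transit:
        y = y0 - height_m * 0.5 - 0.21 * s
        geoms.append(LineString([(x0, y), (x0 + width_m, y - height_m * 0.1)]))
        codes.append(T_FAST)
    if recipe.railway:
        x = x0 + width_m * 0.15
        geoms.append(LineString([(x, y0), (x + width_m * 0.12, y0 - height_m)]))
        codes.append(T_RAIL)
    return TransportLayer(geoms, codes, grid.crs_id)


def _paint_blocks(recipe: CityRecipe, rng, base: np.ndarray,
                  heights: np.ndarray) -> None:
    """Built-up city blocks between the gridded roads: sealed cells, log-normal
    building heights on part of each block, occasional sub-floor heights."""
    R, C = base.shape
    sp = recipe.road_spacing if recipe.road_spacing > 0 else max(R, C)
    lo, hi = recipe.height_range
    for br in range(0, R, sp):
        for bc in range(0, C, sp):
            if rng.random() >= recipe.block_density:
                continue
            r0, c0 = br + 2, bc + 2
            r1, c1 = min(R, br + sp - 1), min(C, bc + sp - 1)
            if r1 - r0 < 2 or c1 - c0 < 2:
                continue
            block = np.s_[r0:r1, c0:c1]
            water_free = base[block] != RAW_WATER
            base[block][water_free] = RAW_SEALED
            with_h = (rng.random((r1 - r0, c1 - c0)) < recipe.building_fill) & water_free
            draws = rng.lognormal(recipe.height_log_mean, recipe.height_log_sigma,
                                  size=(r1 - r0, c1 - c0))
            sub = rng.random((r1 - r0, c1 - c0)) < recipe.sub_floor_fraction
            draws = np.where(sub, rng.uniform(0.3, lo, size=draws.shape),
                             np.clip(draws, lo, hi))
            hview = heights[block]
            hview[with_h] = draws[with_h]
            heights[block] = hview


def generate_city(recipe: CityRecipe,
                  cfg: FusionConfig | None = None) -> CityScene:
    """Generate the four aligned layers and the oracle fused map.

    The transport raster is produced from the centrelines with the configured
    buffer distance and maximum-area assignment; the expected map comes from
    a per-pixel loop over :func:`fuse_pixel`, independent of the vectorised
    :func:`urbanfuse.fusion.fuse` implementation.
    """
    from .transport import buffer_transport, max_area_assign

    cfg = cfg or FusionConfig()
    grid = recipe.grid
    rng = np.random.default_rng(recipe.seed)

    base = _paint_base(recipe, rng)
    water = _paint_water(recipe, rng, base)
    wetness = _paint_wetness(recipe, rng, water)

    vector = _road_network(recipe, grid)
    if len(vector):
        inverse = {v: k for k, v in cfg.transport_mapping.mapping.items()}
        raw_priority = [inverse[cfg.registry.id_of(n)] for n in cfg.transport_priority]
        buffered = buffer_transport(vector, cfg.buffer_distance)
        transport = max_area_assign(buffered, grid, raw_priority)
    else:
        transport = CategoricalRaster(grid, np.zeros(grid.shape, dtype=np.uint8),
                                      nodata_code=0)

    heights = np.full(grid.shape, np.nan)
    _paint_blocks(recipe, rng, base, heights)
    # streets are sealed surface in the base product; no building height there
    road_cells = transport.values != 0
    base[road_cells & (base != RAW_WATER)] = RAW_SEALED
    heights[road_cells] = np.nan
    if recipe.nodata_margin > 0:
        base[:recipe.nodata_margin, :] = NODATA

    base_r = CategoricalRaster(grid, base, nodata_code=NODATA)
    wetness_r = CategoricalRaster(grid, wetness, nodata_code=NODATA)
    heights_m = ContinuousRaster(grid, heights)

    hclass = np.zeros(grid.shape, dtype=np.uint8)
    edges = cfg.height_bin_edges
    for r, c in zip(*np.nonzero(np.isfinite(heights))):
        k = height_to_class(float(heights[r, c]), edges)
        hclass[r, c] = 0 if k is None else k
    heights_class = CategoricalRaster(grid, hclass, nodata_code=0)

    expected = _oracle_map(base_r, wetness_r, heights_m, transport, cfg)
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(expected.values, return_counts=True))}
    return CityScene(grid, base_r, wetness_r, heights_m, heights_class,
                     vector, transport, expected, counts)


def _oracle_map(base: CategoricalRaster, wetness: CategoricalRaster,
                heights_m: ContinuousRaster, transport: CategoricalRaster,
                cfg: FusionConfig) -> CategoricalRaster:
    """Naive per-pixel fusion: the reference the raster pipeline must equal."""
    R, C = base.grid.shape
    out = np.full((R, C), NODATA, dtype=np.uint8)
    trigger = cfg.wet_trigger_codes
    for r in range(R):
        for c in range(C):
            raw = int(base.values[r, c])
            internal = NODATA if raw == base.nodata_code else cfg.base_mapping.lookup(raw)
            wet = int(wetness.values[r, c]) in trigger
            h = float(heights_m.values[r, c])
            hk = height_to_class(h, cfg.height_bin_edges)
            traw = int(transport.values[r, c])
            t = None if traw == transport.nodata_code else cfg.transport_mapping.lookup(traw)
            out[r, c] = fuse_pixel(PixelState(internal, wet, hk, t), cfg)
    return CategoricalRaster(base.grid, out, nodata_code=NODATA)


def pairs_from_matrix(cm: ConfusionMatrix, seed: int) -> ValidationPoints:
    """Realise a count matrix as labelled (map, reference) point records.

    Exactly n_ij records carry (map=i, ref=j); the order is shuffled by the
    seed.  Cross-tabulating the output recovers the matrix exactly.
    """
    rng = np.random.default_rng(seed)
    maps, refs = [], []
    for i, mlabel in enumerate(cm.labels):
        for j, rlabel in enumerate(cm.labels):
            n = int(cm.counts[i, j])
            maps.extend([mlabel] * n)
            refs.extend([rlabel] * n)
    order = rng.permutation(len(maps))
    df = pd.DataFrame({
        "x": np.nan, "y": np.nan,
        "map_class": [maps[i] for i in order],
        "ref_class": [refs[i] for i in order],
    })
    return ValidationPoints(df)
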