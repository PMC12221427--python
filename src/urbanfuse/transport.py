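"""Vector-to-raster conversion of the transport network.

Road and rail centrelines are buffered (default 7 m, round caps and joins) so
that thin linear features survive conversion to a 10 m grid, then rasterized
by *maximum area cell assignment*: each cell receives the transport class
whose dissolved geometry covers the largest area within the cell square.
Per-class geometries are dissolved before the comparison so several small
same-class features aggregate; exact area ties are resolved by a configurable
priority order (default: railways > fast transit roads > other roads, so the
rarer, narrower feature survives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import CodeError, GridError
from .grid import CategoricalRaster, GridSpec
from .io import TransportLayer

#: Segments per quarter circle used for polygonal buffer approximation.
QUAD_SEGS = 16

#: Code for cells with no transport coverage in the output raster.
NO_TRANSPORT = 0


def dissolve_by_class(layer: TransportLayer) -> dict[int, BaseGeometry]:
    """Union of all geometries per transport class code."""
    groups: dict[int, list[BaseGeometry]] = {}
    for geom, code in zip(layer.geometries, layer.class_codes):
        groups.setdefault(int(code), []).append(geom)
    return {code: unary_union(geoms) for code, geoms in groups.items()}


def buffer_transport(layer: TransportLayer, distance: float,
                     quad_segs: int = QUAD_SEGS) -> TransportLayer:
    """Replace every geometry by its polygonal buffer and dissolve per class.

    Round caps and joins; ``quad_segs`` segments approximate each quarter
    circle.  ``distance`` 0 leaves polygons unchanged (lines degenerate to
    empty and are rejected by the layer invariant).
    """
    if distance < 0:
        raise CodeError(f"buffer distance must be >= 0, got {distance}")
    buffered = TransportLayer(
        [g if distance == 0 and g.area > 0
         else g.buffer(distance, quad_segs=quad_segs)
         for g in layer.geometries],
        list(layer.class_codes),
        layer.crs_id,
    )
    unions = dissolve_by_class(buffered)
    codes = sorted(unions)
    return TransportLayer([unions[c] for c in codes], codes, layer.crs_id)


@dataclass
class CoverageTable:
    """Intersection areas (m²) between cell squares and per-class geometry.

    ``areas[k]`` is the n_rows x n_cols area raster for ``codes[k]``.
    """

    grid: GridSpec
    codes: list[int]
    areas: np.ndarray  # shape (k, n_rows, n_cols)

    def fractions(self) -> np.ndarray:
        return self.areas / self.grid.cell_size ** 2

    def area_of(self, code: int) -> np.ndarray:
        return self.areas[self.codes.index(code)]


def _class_coverage(geom: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Per-cell intersection area between ``geom`` and the cell squares."""
    out = np.zeros(grid.shape)
    if geom.is_empty:
        return out
    s = grid.cell_size
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(np.floor((minx - grid.origin_x) / s)))
    c1 = min(grid.n_cols, int(np.ceil((maxx - grid.origin_x) / s)))
    r0 = max(0, int(np.floor((grid.origin_y - maxy) / s)))
    r1 = min(grid.n_rows, int(np.ceil((grid.origin_y - miny) / s)))
    if c0 >= c1 or r0 >= r1:
        return out
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    cc, rr = np.meshgrid(cols, rows)
    x0 = grid.origin_x + cc * s
    y1 = grid.origin_y - rr * s
    boxes = shapely.box(x0.ravel(), (y1 - s).ravel(), (x0 + s).ravel(), y1.ravel())
    inter = shapely.area(shapely.intersection(boxes, geom))
    out[r0:r1, c0:c1] = inter.reshape(len(rows), len(cols))
    return out


def coverage_fractions(layer: TransportLayer, grid: GridSpec) -> CoverageTable:
    """Coverage areas per (cell, class) for a polygonal (buffered) layer.

    The maximum-area assignment is exactly reproducible from this table.
    """
    unions = dissolve_by_class(layer)
    codes = sorted(unions)
    areas = np.stack([_class_coverage(unions[c], grid) for c in codes]) \
        if codes else np.zeros((0,) + grid.shape)
    return CoverageTable(grid, codes, areas)


def max_area_assign(layer: TransportLayer, grid: GridSpec,
                    priority: Sequence[int],
                    sentinel: int = NO_TRANSPORT) -> CategoricalRaster:
    """Rasterize a polygonal transport layer by maximum area cell assignment.

    Each cell receives the class whose dissolved geometry intersects the cell
    square with the strictly largest area; any strictly positive coverage is
    eligible (no minimum-fraction cutoff).  Exact ties fall to the earliest
    class in ``priority``; zero-coverage cells get ``sentinel``.
    """
    present = set(layer.class_codes)
    missing = present - set(priority)
    if missing:
        raise CodeError(f"priority order does not cover transport codes {sorted(missing)}")
    table = coverage_fractions(layer, grid)
    out = np.full(grid.shape, sentinel, dtype=np.uint8)
    if table.codes:
        order = [c for c in priority if c in table.codes]
        stacked = np.stack([table.area_of(c) for c in order])
        best = np.argmax(stacked, axis=0)  # first max -> highest priority wins ties
        covered = stacked.max(axis=0) > 0.0
        code_arr = np.asarray(order, dtype=np.uint8)
        out[covered] = code_arr[best[covered]]
    return CategoricalRaster(grid, out, nodata_code=sentinel)
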