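"""Raster geometry and categorical raster containers.

All rasters in the pipeline live on a shared axis-aligned grid in a projected,
metre-based CRS.  Cells are addressed 0-based, row-major from the top-left
corner; cell (r, c) covers the half-open square

    [origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]

with s the cell edge length in metres.  The default cell size is 10 m, the
resolution of the Copernicus thematic products the pipeline emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

#: Default projected CRS for synthetic fixtures: ETRS89-extended / LAEA Europe,
#: the equal-area metre CRS in which the pan-European Copernicus products ship.
DEFAULT_CRS = 3035

#: Reserved nodata code for 8-bit categorical rasters.
NODATA = 255


@dataclass(frozen=True)
class GridSpec:
    """Georeferenced raster geometry: CRS, top-left origin, cell size, shape."""

    crs_id: int = DEFAULT_CRS
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 10.0
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(
                f"grid must have at least one row and column, got "
                f"{self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of cell (row, col) in map coordinates."""
        s = self.cell_size
        minx = self.origin_x + col * s
        maxy = self.origin_y - row * s
        return (minx, maxy - s, minx + s, maxy)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size
        return (
            self.origin_x + (col + 0.5) * s,
            self.origin_y - (row + 0.5) * s,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell index containing map point (x, y) under the half-open convention."""
        s = self.cell_size
        col = int(np.floor((x - self.origin_x) / s))
        row = int(np.floor((self.origin_y - y) / s))
        # top edge belongs to row 0
        if y == self.origin_y:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise GridError(f"point ({x}, {y}) lies outside the grid")
        return (row, col)

    def contains_point(self, x: float, y: float) -> bool:
        s = self.cell_size
        return (
            self.origin_x <= x < self.origin_x + self.n_cols * s
            and self.origin_y - self.n_rows * s < y <= self.origin_y
        )


@dataclass(frozen=True)
class AlignmentVerdict:
    """Outcome of a grid-compatibility check; falsy when misaligned."""

    aligned: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.aligned


def check_alignment(a: GridSpec, b: GridSpec) -> AlignmentVerdict:
    """Decide whether two grids lie on one common lattice.

    Aligned means: same CRS, same cell size, and origins offset by integer
    multiples of the cell size.  Shapes may differ; alignment is about the
    lattice, not the extent.  Total, symmetric and reflexive.
    """
    if a.crs_id != b.crs_id:
        return AlignmentVerdict(False, f"crs: {a.crs_id} != {b.crs_id}")
    if a.cell_size != b.cell_size:
        return AlignmentVerdict(False, f"cell_size: {a.cell_size} != {b.cell_size}")
    s = a.cell_size
    for name, da in (("origin_x", a.origin_x - b.origin_x),
                     ("origin_y", a.origin_y - b.origin_y)):
        ratio = da / s
        if abs(ratio - round(ratio)) > 1e-9:
            return AlignmentVerdict(False, f"origin: {name} offset {da} m is not a multiple of {s} m")
    return AlignmentVerdict(True)


@dataclass
class CategoricalRaster:
    """A grid of integer class codes with a reserved nodata sentinel."""

    grid: GridSpec
    values: np.ndarray
    nodata_code: int = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise GridError(f"categorical raster requires integer codes, got {self.values.dtype}")
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"value shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(self.grid, self.values.copy(), self.nodata_code)

    def tally(self) -> dict[int, int]:
        """Cell count per code, nodata included under its own key."""
        codes, counts = np.unique(self.values, return_counts=True)
        return {int(k): int(v) for k, v in zip(codes, counts)}


@dataclass
class ContinuousRaster:
    """A float-valued layer on the same grid model (used for metric building heights).

    NaN is the nodata sentinel.
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"value shape {self.values.shape} does not match grid {self.grid.shape}"
            )


def make_raster(
    grid: GridSpec,
    fill_code: int,
    registry=None,
    nodata_code: int = NODATA,
) -> CategoricalRaster:
    """Create a constant raster on ``grid`` filled with ``fill_code``.

    When a :class:`~urbanfuse.classes.ClassRegistry` is given, the fill code
    must be the nodata sentinel or a registered class id.
    """
    if registry is not None and fill_code != nodata_code and fill_code not in registry:
        from .errors import CodeError

        raise CodeError(f"fill code {fill_code} is not registered")
    values = np.full(grid.shape, fill_code, dtype=np.uint8 if 0 <= fill_code <= 255 else np.int64)
    return CategoricalRaster(grid, values, nodata_code)
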