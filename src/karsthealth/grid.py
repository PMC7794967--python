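"""Analysis fishnet and zonal aggregation from rasters to grid cells.

The assessment unit is a square fishnet cell (2 km by default) laid over the
study extent from its north-west corner, enumerated row-major with stable
integer ids.  Raster pixels are assigned to the unique cell containing their
center (half-open cell intervals), so no pixel is double-counted or dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raster import Raster

MISSING = np.nan


@dataclass
class Grid:
    """Square fishnet over a rectangular extent.

    Cells are enumerated row-major from the NW corner; cell id
    ``r * n_cols + c``.  Cells extending past the extent (when the extent is
    not a multiple of the cell size) are kept and flagged in
    ``boundary_flags``.
    """

    x_min: float
    y_max: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "local-metric"
    #: True where the cell sticks out of the nominal extent
    boundary_flags: np.ndarray = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, id order."""
        r, c = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = self.x_min + (c + 0.5) * self.cell_size
        y = self.y_max - (r + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        r, c = divmod(int(cell_id), self.n_cols)
        x0 = self.x_min + c * self.cell_size
        y1 = self.y_max - r * self.cell_size
        return (x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def cell_of_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell id containing each point; -1 outside the grid.

        A cell covers the half-open box [x0, x0+s) x (y1-s, y1], so a point
        on an interior edge belongs to exactly one cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(np.int64)
        # cell interval is (y_top - s, y_top]: top edge of the grid inclusive
        row = np.floor((self.y_max - y) / self.cell_size).astype(np.int64)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row * self.n_cols + col, -1)


def build_fishnet(extent: tuple[float, float, float, float],
                  cell_size_m: float = 2000.0,
                  crs: str = "local-metric") -> Grid:
    """Build the analysis fishnet over ``extent`` = (x_min, y_min, x_max, y_max).

    The number of cells per axis is the ceiling of extent/size, so an extent
    that is not a multiple of the cell size gets edge cells flagged as
    truncated by the study boundary.  An extent smaller than one cell yields
    a single-cell grid.
    """
    x_min, y_min, x_max, y_max = map(float, extent)
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    if x_max <= x_min or y_max <= y_min:
        raise ValueError("degenerate extent")
    n_cols = max(1, math.ceil((x_max - x_min) / cell_size_m - 1e-9))
    n_rows = max(1, math.ceil((y_max - y_min) / cell_size_m - 1e-9))
    grid = Grid(x_min=x_min, y_max=y_max, cell_size=cell_size_m,
                n_rows=n_rows, n_cols=n_cols, crs=crs)
    r, c = np.divmod(np.arange(grid.n_cells), n_cols)
    flags = ((c + 1) * cell_size_m > (x_max - x_min) + 1e-9) | (
        (r + 1) * cell_size_m > (y_max - y_min) + 1e-9)
    grid.boundary_flags = flags
    return grid


@dataclass
class IndicatorLayer:
    """One real value (NaN = missing) per grid cell, for one indicator/epoch."""

    name: str
    epoch: int | None
    values: np.ndarray
    grid: Grid | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.grid is not None and self.values.size != self.grid.n_cells:
            raise ValueError("values length must equal number of grid cells")

    def with_values(self, values: np.ndarray, name: str | None = None
                    ) -> "IndicatorLayer":
        return IndicatorLayer(name or self.name, self.epoch,
                              np.asarray(values, dtype=float), self.grid)


def _pixel_cells(raster: Raster, grid: Grid) -> np.ndarray:
    """Flat array: grid cell id of every pixel center (-1 outside grid)."""
    if raster.crs != grid.crs:
        raise ValueError(
            f"CRS mismatch: raster {raster.crs!r} vs grid {grid.crs!r}")
    xs, ys = raster.pixel_centers()
    return grid.cell_of_points(xs.ravel(), ys.ravel())


def zonal_reduce(raster: Raster, grid: Grid, values: np.ndarray,
                 valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum ``values`` and count valid pixels per grid cell.

    Returns (sums, counts) arrays of length n_cells; pixels outside the grid
    or invalid are ignored.
    """
    cells = _pixel_cells(raster, grid)
    keep = valid.ravel() & (cells >= 0)
    sums = np.bincount(cells[keep], weights=values.ravel()[keep],
                       minlength=grid.n_cells)
    counts = np.bincount(cells[keep], minlength=grid.n_cells)
    return sums, counts


def zonal_fraction(raster: Raster, grid: Grid, class_codes: set[int],
                   name: str = "fraction", epoch: int | None = None
                   ) -> IndicatorLayer:
    """Per cell: fraction of valid pixels whose code is in ``class_codes``."""
    valid = raster.valid_mask()
    member = np.isin(raster.data, list(class_codes)).astype(float)
    sums, counts = zonal_reduce(raster, grid, member, valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, sums / counts, MISSING)
    return IndicatorLayer(name, epoch, frac, grid)


def zonal_mean(raster: Raster, grid: Grid, name: str = "mean",
               epoch: int | None = None) -> IndicatorLayer:
    """Per cell: mean of valid pixel values whose centers fall in the cell."""
    valid = raster.valid_mask()
    data = np.where(valid, raster.data.astype(float), 0.0)
    sums, counts = zonal_reduce(raster, grid, data, valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, MISSING)
    return IndicatorLayer(name, epoch, mean, grid)


def slope_deg(dem: Raster) -> Raster:
    """Per-pixel slope in degrees, Horn's 3x3 finite-difference estimator.

    Border pixels use edge replication.  A single-pixel DEM is flat by
    definition.
    """
    z = np.asarray(dem.data, dtype=float)
    if z.size == 1:
        return dem.with_data(np.zeros_like(z), nodata=-9999.0, legend=None)
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                  f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1]; i = zp[2:, 2:]
    cs = dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.with_data(slope.astype(np.float64), nodata=-9999.0, legend=None)
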