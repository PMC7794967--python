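"""The twelve per-cell indicators of the pressure-state-response system.

Pressure: population density, man-made interference, land reclamation rate,
proportion of steeply sloping (>25 deg) farmland.  State: vegetation
coverage, Shannon evenness, Shannon diversity, contagion, ecological
resilience, ecosystem-service value.  Response: proportion of forest land,
rocky-desertification sensitivity.

Interference, resilience and ecosystem-service value share one construction:
an area-weighted sum of per-class coefficients over the cell's land-cover
composition.  The coefficient tables are configuration, not constants of the
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, IndicatorLayer, zonal_fraction, zonal_mean, zonal_reduce
from .raster import (FOREST_CLASSES, LANDUSE_LEGEND, VEGETATION_CLASSES,
                     Raster)

_CODE = {name: code for code, name in LANDUSE_LEGEND.items()}


def _codes(names) -> set[int]:
    return {_CODE[n] for n in names}


# --------------------------------------------------------------------------
# area-weighted coefficient indices (interference H, resilience ERI, ESV)

#: hemeroby-style human-interference coefficients: higher = more disturbed
DEFAULT_INTERFERENCE = {
    "built-up": 1.0,
    "farmland": 0.6,
    "unused": 0.4,
    "low-density grassland": 0.3,
    "mid-density grassland": 0.25,
    "high-density grassland": 0.2,
    "shrubland": 0.2,
    "forestland": 0.1,
    "water": 0.05,
}

#: relative capacity to absorb disturbance and recover
DEFAULT_RESILIENCE = {
    "forestland": 1.0,
    "shrubland": 0.8,
    "high-density grassland": 0.7,
    "water": 0.8,
    "mid-density grassland": 0.5,
    "low-density grassland": 0.3,
    "farmland": 0.3,
    "unused": 0.1,
    "built-up": 0.05,
}

#: per-km^2 ecosystem-service value weights following the common Chinese
#: equivalent-value pattern (water highest, forest high, built-up nil);
#: relative units — min-max normalisation downstream absorbs the scale
DEFAULT_ESV = {
    "water": 4.09,
    "forestland": 1.93,
    "shrubland": 1.31,
    "high-density grassland": 0.94,
    "mid-density grassland": 0.64,
    "low-density grassland": 0.36,
    "farmland": 0.62,
    "unused": 0.04,
    "built-up": 0.0,
}

_DEFAULT_COEFFS = {
    "interference": DEFAULT_INTERFERENCE,
    "resilience": DEFAULT_RESILIENCE,
    "esv": DEFAULT_ESV,
}


@dataclass
class CoefficientTable:
    """Per-class coefficients for one area-weighted index."""

    purpose: str
    coeff: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.purpose not in _DEFAULT_COEFFS:
            raise ValueError(f"unknown purpose {self.purpose!r}")
        if self.coeff is None:
            self.coeff = dict(_DEFAULT_COEFFS[self.purpose])

    def validate_against(self, legend: dict[int, str]) -> None:
        missing = [n for n in legend.values() if n not in self.coeff]
        if missing:
            raise ValueError(
                f"{self.purpose} coefficients missing for {missing}")


def area_weighted_index(lu: Raster, grid: Grid, table: CoefficientTable,
                        epoch: int | None = None) -> IndicatorLayer:
    """Per cell: sum over classes of coeff(class) x area fraction of class.

    Equivalently the mean of the per-pixel coefficient over valid pixels.
    """
    table.validate_against(lu.legend)
    coeff_by_code = np.zeros(max(lu.legend) + 1)
    for code, name in lu.legend.items():
        coeff_by_code[code] = table.coeff[name]
    mapped = coeff_by_code[lu.data.astype(np.int64).clip(min=0)]
    sums, counts = zonal_reduce(lu, grid, mapped, lu.valid_mask())
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(counts > 0, sums / counts, np.nan)
    return IndicatorLayer(table.purpose, epoch, vals, grid)


# --------------------------------------------------------------------------
# simple zonal indicators

def pop_density(pop: Raster, grid: Grid, epoch: int | None = None
                ) -> IndicatorLayer:
    """Mean population density (persons/km^2) per cell."""
    return zonal_mean(pop, grid, name="pop_density", epoch=epoch)


def reclamation_rate(lu: Raster, grid: Grid, epoch: int | None = None
                     ) -> IndicatorLayer:
    """Fraction of the cell under farmland."""
    layer = zonal_fraction(lu, grid, _codes({"farmland"}),
                           name="reclamation_rate", epoch=epoch)
    return layer


def vegetation_coverage(lu: Raster, grid: Grid, epoch: int | None = None
                        ) -> IndicatorLayer:
    """Fraction of the cell under vegetated cover (forest, shrub, grassland).

    A land-cover proxy: no reflectance-based vegetation index is involved.
    """
    return zonal_fraction(lu, grid, _codes(VEGETATION_CLASSES),
                          name="vegetation_coverage", epoch=epoch)


def forest_proportion(lu: Raster, grid: Grid, epoch: int | None = None
                      ) -> IndicatorLayer:
    """Fraction of the cell under forest or shrubland."""
    return zonal_fraction(lu, grid, _codes(FOREST_CLASSES),
                          name="forest_proportion", epoch=epoch)


def steep_farmland_ratio(lu: Raster, slope: Raster, grid: Grid,
                         threshold_deg: float = 25.0,
                         epoch: int | None = None) -> IndicatorLayer:
    """Fraction of the cell that is farmland on slopes above the threshold.

    Denominator is all pixels in the cell, so cells without farmland score
    zero pressure rather than missing.
    """
    if not lu.same_registration(slope):
        raise ValueError("land use and slope rasters are not co-registered")
    steep_farm = ((lu.data == _CODE["farmland"])
                  & (slope.data > threshold_deg)).astype(float)
    sums, counts = zonal_reduce(lu, grid, steep_farm, lu.valid_mask())
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(counts > 0, sums / counts, np.nan)
    return IndicatorLayer("steep_farmland_ratio", epoch, vals, grid)


# --------------------------------------------------------------------------
# landscape metrics (each 2 km cell is treated as one landscape)

def shdi(proportions: np.ndarray) -> float:
    """Shannon diversity -sum p ln p over classes with p > 0."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return float("nan")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    return float(-(p * np.log(p)).sum())


def shei(proportions: np.ndarray) -> float:
    """Shannon evenness: SHDI / ln(classes present); 0 for a single class."""
    p = np.asarray(proportions, dtype=float)
    m = int((p > 0).sum())
    if m <= 1:
        return 0.0
    return shdi(p) / np.log(m)


def contag(pixels: np.ndarray) -> float:
    """Contagion (0-100] of a categorical pixel block.

    Adjacency g_ik uses the 4-neighbour rule with double counting (each
    adjacent pair tallied in both directions).  With composition P_i and
    m classes present:

        100 * [1 + sum_i sum_k q_ik ln q_ik / (2 ln m)],
        q_ik = P_i * g_ik / sum_k g_ik

    Returns 100 for a single-class (or single-pixel) landscape — maximal
    aggregation by definition.
    """
    px = np.asarray(pixels)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("pixels must be a non-empty 2-D block")
    classes = np.unique(px)
    m = classes.size
    if m == 1 or px.size == 1:
        return 100.0
    index = {c: i for i, c in enumerate(classes)}
    idx = np.vectorize(index.get)(px)
    g = np.zeros((m, m))
    # horizontal and vertical neighbour pairs, both directions
    for a, b in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
        np.add.at(g, (a.ravel(), b.ravel()), 1)
        np.add.at(g, (b.ravel(), a.ravel()), 1)
    if g.sum() == 0:  # no adjacencies at all (degenerate 1-pixel rows)
        return 100.0
    p_i = np.bincount(idx.ravel(), minlength=m) / idx.size
    row_tot = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = p_i[:, None] * np.where(row_tot > 0, g / row_tot, 0.0)
    terms = q[q > 0]
    val = 100.0 * (1.0 + (terms * np.log(terms)).sum() / (2.0 * np.log(m)))
    return float(val)


def _cell_pixel_blocks(lu: Raster, grid: Grid):
    """Yield (cell_id, 2-D pixel block) for every cell with valid pixels.

    Assumes the raster nests in the grid (the nominal 1 km-in-2 km case);
    blocks are cut by pixel-center membership.
    """
    from .grid import _pixel_cells

    cells = _pixel_cells(lu, grid).reshape(lu.shape)
    valid = lu.valid_mask()
    n_rows, n_cols = lu.shape
    for cid in np.unique(cells[cells >= 0]):
        mask = (cells == cid) & valid
        if not mask.any():
            continue
        rows = np.where(mask.any(axis=1))[0]
        cols = np.where(mask.any(axis=0))[0]
        block = lu.data[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        yield int(cid), block


def landscape_metrics(lu: Raster, grid: Grid, epoch: int | None = None
                      ) -> dict[str, IndicatorLayer]:
    """SHDI, SHEI and CONTAG per grid cell."""
    shdi_v = np.full(grid.n_cells, np.nan)
    shei_v = np.full(grid.n_cells, np.nan)
    cont_v = np.full(grid.n_cells, np.nan)
    for cid, block in _cell_pixel_blocks(lu, grid):
        vals = block[block != lu.nodata]
        counts = np.bincount(vals.astype(np.int64))
        p = counts[counts > 0] / vals.size
        shdi_v[cid] = shdi(p)
        shei_v[cid] = shei(p)
        cont_v[cid] = contag(block)
    return {
        "shdi": IndicatorLayer("shdi", epoch, shdi_v, grid),
        "shei": IndicatorLayer("shei", epoch, shei_v, grid),
        "contag": IndicatorLayer("contag", epoch, cont_v, grid),
    }


# --------------------------------------------------------------------------
# rocky-desertification sensitivity

@dataclass
class RdsRule:
    """Banded scoring rule for karst rocky-desertification susceptibility.

    Sensitivity rises with slope, falls with vegetation coverage, and only
    applies on carbonate lithology.  Per cell:

        carbonate_fraction * (slope_score + coverage_score) / max_score

    where each score is a band lookup at the cell-mean slope and the cell
    vegetation coverage, and max_score is the largest attainable sum, so the
    result lies in [0, 1].
    """

    #: upper band edges (deg); a value falls in the first band whose edge
    #: it does not exceed, with one implicit open top band
    slope_edges: tuple[float, ...] = (5.0, 15.0, 25.0)
    slope_scores: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    #: upper edges for vegetation coverage in [0, 1]
    coverage_edges: tuple[float, ...] = (0.3, 0.5, 0.7)
    #: low coverage = high sensitivity
    coverage_scores: tuple[float, ...] = (4.0, 3.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.slope_scores) != len(self.slope_edges) + 1:
            raise ValueError("need one slope score per band")
        if len(self.coverage_scores) != len(self.coverage_edges) + 1:
            raise ValueError("need one coverage score per band")
        if (min(self.slope_scores) < 0 or min(self.coverage_scores) < 0):
            raise ValueError("band scores must be non-negative")
        if (list(self.slope_edges) != sorted(self.slope_edges)
                or list(self.coverage_edges) != sorted(self.coverage_edges)):
            raise ValueError("band edges must be increasing")

    @property
    def max_score(self) -> float:
        return max(self.slope_scores) + max(self.coverage_scores)

    def slope_score(self, slope_deg: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.slope_edges, slope_deg, side="left")
        return np.asarray(self.slope_scores)[idx]

    def coverage_score(self, coverage: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.coverage_edges, coverage, side="left")
        return np.asarray(self.coverage_scores)[idx]


def rds_sensitivity(slope: Raster, coverage: IndicatorLayer,
                    carbonate_mask: Raster, grid: Grid,
                    rule: RdsRule | None = None,
                    epoch: int | None = None) -> IndicatorLayer:
    """Rocky-desertification sensitivity in [0, 1] per cell."""
    rule = rule or RdsRule()
    mean_slope = zonal_mean(slope, grid).values
    carb = zonal_mean(carbonate_mask.with_data(
        carbonate_mask.data.astype(float), nodata=-1.0), grid).values
    score = np.full(grid.n_cells, np.nan)
    ok = np.isfinite(mean_slope) & np.isfinite(coverage.values) & np.isfinite(carb)
    score[ok] = (carb[ok]
                 * (rule.slope_score(mean_slope[ok])
                    + rule.coverage_score(coverage.values[ok]))
                 / rule.max_score)
    return IndicatorLayer("rds_sensitivity", epoch, score, grid)
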