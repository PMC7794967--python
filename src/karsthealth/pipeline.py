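"""End-to-end assessment pipeline over a scene.

Chains the stages: per-epoch indicator computation on the 2 km fishnet,
pooled normalisation and weighted composition into P/S/R and the health
index, natural-breaks classification, the urbanization composite, bivariate
Moran/LISA between urbanization and health, and mine-buffer zonal
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indicators as ind
from .composite import ESHResult, WeightScheme, classify_esh, compute_esh
from .grid import Grid, IndicatorLayer, build_fishnet, slope_deg, zonal_mean
from .scene import SyntheticScene
from .spatial import (LISAResult, MoranResult, SpatialWeights,
                      bivariate_lisa, bivariate_moran, build_weights,
                      moran_permutation_test)
from .urbanization import UrbanizationLayer, clp, urbanization_index
from .zones import DEFAULT_RADII_M, buffer_union, mine_health_counts, zone_stats


@dataclass
class AssessmentResult:
    grid: Grid
    indicator_series: dict[str, list[IndicatorLayer]]
    esh_results: list[ESHResult]
    breaks: np.ndarray
    urbanization: list[UrbanizationLayer]
    weights: SpatialWeights
    moran: list[MoranResult]
    lisa: list[LISAResult]
    zone_tables: dict[float, pd.DataFrame]
    mine_counts: pd.DataFrame | None

    def moran_table(self) -> pd.DataFrame:
        """Global association summary in the layout of a per-year table."""
        return pd.DataFrame({
            "year": [r.esh.epoch for r in self.esh_results],
            "moran_i": [m.i_obs for m in self.moran],
            "z_value": [m.z_value for m in self.moran],
            "p_value": [m.pseudo_p for m in self.moran],
        })


def compute_indicators(scene: SyntheticScene, grid: Grid,
                       rds_rule: ind.RdsRule | None = None
                       ) -> dict[str, list[IndicatorLayer]]:
    """All twelve indicator series (one layer per epoch) for a scene."""
    slope = slope_deg(scene.dem)
    series: dict[str, list[IndicatorLayer]] = {name: [] for name in (
        "pop_density", "interference", "reclamation_rate",
        "steep_farmland_ratio", "vegetation_coverage", "shei", "shdi",
        "contag", "resilience", "esv", "forest_proportion",
        "rds_sensitivity")}
    tables = {p: ind.CoefficientTable(p)
              for p in ("interference", "resilience", "esv")}
    for k, epoch in enumerate(scene.params.epochs):
        lu = scene.landuse_series[k]
        pop = scene.pop_series[k]
        series["pop_density"].append(ind.pop_density(pop, grid, epoch))
        for purpose in tables:
            series[purpose].append(
                ind.area_weighted_index(lu, grid, tables[purpose], epoch))
        series["reclamation_rate"].append(
            ind.reclamation_rate(lu, grid, epoch))
        series["steep_farmland_ratio"].append(
            ind.steep_farmland_ratio(lu, slope, grid, epoch=epoch))
        veg = ind.vegetation_coverage(lu, grid, epoch)
        series["vegetation_coverage"].append(veg)
        metrics = ind.landscape_metrics(lu, grid, epoch)
        for name in ("shdi", "shei", "contag"):
            series[name].append(metrics[name])
        series["forest_proportion"].append(
            ind.forest_proportion(lu, grid, epoch))
        series["rds_sensitivity"].append(ind.rds_sensitivity(
            slope, veg, scene.carbonate_mask, grid, rds_rule, epoch))
    return series


def run_assessment(scene: SyntheticScene,
                   weight_scheme: WeightScheme | None = None,
                   cell_size_m: float = 2000.0,
                   n_perm: int = 999,
                   alpha: float = 0.05,
                   radii_m: tuple[float, ...] = DEFAULT_RADII_M,
                   seed: int | None = None) -> AssessmentResult:
    """Run the full grid-based assessment on a scene."""
    grid = build_fishnet(scene.params.extent, cell_size_m,
                         crs=scene.dem.crs)
    series = compute_indicators(scene, grid)
    esh_results = compute_esh(series, weight_scheme)
    breaks = classify_esh(esh_results)

    clp_layers = [clp(lu, grid, e) for lu, e in
                  zip(scene.landuse_series, scene.params.epochs)]
    gdp_layers = [zonal_mean(g, grid, name="gdp_per_capita", epoch=e)
                  for g, e in zip(scene.gdp_series, scene.params.epochs)]
    urban = urbanization_index(series["pop_density"], gdp_layers, clp_layers)

    # association between urbanization and health, per epoch, on cells
    # where both are defined in every epoch (one shared weight matrix)
    valid = np.ones(grid.n_cells, dtype=bool)
    for res, ul in zip(esh_results, urban):
        valid &= np.isfinite(res.esh.values) & np.isfinite(ul.u.values)
    w = build_weights(grid, "queen", valid_mask=valid)
    rng = np.random.default_rng(seed)
    moran, lisa = [], []
    for res, ul in zip(esh_results, urban):
        x = ul.u.values[w.ids]
        y = res.esh.values[w.ids]
        s1, s2 = (int(rng.integers(2**31)), int(rng.integers(2**31)))
        moran.append(moran_permutation_test(x, y, w, n_perm=n_perm, seed=s1))
        lisa.append(bivariate_lisa(x, y, w, n_perm=n_perm, alpha=alpha,
                                   seed=s2))

    zone_tables: dict[float, pd.DataFrame] = {}
    mine_counts = None
    if scene.mines.shape[0] > 0:
        for radius in radii_m:
            zone = buffer_union(scene.mines, radius)
            zone_tables[radius] = zone_stats(zone, esh_results, grid)
        mine_counts = mine_health_counts(scene.mines, esh_results, grid)

    return AssessmentResult(
        grid=grid, indicator_series=series, esh_results=esh_results,
        breaks=breaks, urbanization=urban, weights=w, moran=moran,
        lisa=lisa, zone_tables=zone_tables, mine_counts=mine_counts)
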