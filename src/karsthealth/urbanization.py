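"""Composite urbanization level per grid cell.

Urbanization is summarised by three positive-direction components —
population density, per-capita GDP and construction-land proportion — each
min-max normalised over the multi-epoch pool and averaged (equal weights by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composite import normalize
from .grid import Grid, IndicatorLayer, zonal_fraction, zonal_mean
from .raster import LANDUSE_LEGEND, Raster

_BUILT_CODE = {name: code for code, name in LANDUSE_LEGEND.items()}["built-up"]


def clp(lu: Raster, grid: Grid, epoch: int | None = None) -> IndicatorLayer:
    """Construction-land proportion: built-up fraction of the cell."""
    return zonal_fraction(lu, grid, {_BUILT_CODE}, name="clp", epoch=epoch)


@dataclass
class UrbanizationLayer:
    """Per-epoch urbanization components and composite."""

    epoch: int | None
    q_pop: IndicatorLayer
    q_gdp: IndicatorLayer
    q_clp: IndicatorLayer
    u: IndicatorLayer


def urbanization_index(pop_layers: list[IndicatorLayer],
                       gdp_layers: list[IndicatorLayer],
                       clp_layers: list[IndicatorLayer],
                       weights: tuple[float, float, float] = (1/3, 1/3, 1/3),
                       ) -> list[UrbanizationLayer]:
    """Per-epoch urbanization level U = weighted mean of normalised components.

    Components are normalised with the positive min-max formula, pooled over
    all epochs (the same policy as the health composite).  A cell missing any
    component is missing in U.
    """
    if not (len(pop_layers) == len(gdp_layers) == len(clp_layers)):
        raise ValueError("component series must cover the same epochs")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("component weights must be non-negative and sum to 1")
    q_pop = normalize(pop_layers, "positive")
    q_gdp = normalize(gdp_layers, "positive")
    q_clp = normalize(clp_layers, "positive")
    out = []
    for qp, qg, qc in zip(q_pop, q_gdp, q_clp):
        u = w[0] * qp.values + w[1] * qg.values + w[2] * qc.values
        out.append(UrbanizationLayer(
            epoch=qp.epoch, q_pop=qp, q_gdp=qg, q_clp=qc,
            u=qp.with_values(u, name="urbanization")))
    return out
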