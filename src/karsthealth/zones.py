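"""Mine-buffer zonal analysis.

Buffers of configurable radii (2/3/6 km by default) are drawn around every
mine point and dissolved into one zone per radius; per epoch, the pressure,
state, response and composite-health means are taken over grid cells whose
centers fall inside the zone, and each mine is assigned the health class of
the cell containing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from .composite import HEALTH_CLASSES, ESHResult
from .grid import Grid

DEFAULT_RADII_M = (2000.0, 3000.0, 6000.0)


@dataclass
class BufferZone:
    radius_m: float
    geometry: shapely.Geometry
    n_mines: int

    @property
    def area(self) -> float:
        return self.geometry.area


def buffer_union(mines: np.ndarray, radius_m: float,
                 quad_segs: int = 64) -> BufferZone:
    """Dissolved union of disks of ``radius_m`` around each mine point."""
    mines = np.asarray(mines, dtype=float).reshape(-1, 2)
    if mines.shape[0] == 0:
        raise ValueError("no mine points supplied")
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    disks = [Point(x, y).buffer(radius_m, quad_segs=quad_segs)
             for x, y in mines]
    return BufferZone(radius_m=radius_m, geometry=unary_union(disks),
                      n_mines=mines.shape[0])


def cells_in_zone(zone: BufferZone, grid: Grid) -> np.ndarray:
    """Ids of grid cells whose centers fall inside the zone geometry."""
    centers = grid.cell_centers()
    inside = shapely.contains_xy(zone.geometry, centers[:, 0], centers[:, 1])
    return np.where(inside)[0]


def zone_stats(zone: BufferZone, results: list[ESHResult], grid: Grid
               ) -> pd.DataFrame:
    """Unweighted zonal means of P, S, R and the health index per epoch.

    Cells with missing values are excluded; a zone containing no cell
    centers yields all-NaN rows with a warning.
    """
    ids = cells_in_zone(zone, grid)
    if ids.size == 0:
        warnings.warn(f"{zone.radius_m/1000:g} km zone contains no cell "
                      "centers; statistics are missing")
    rows = []
    for res in results:
        row = {"epoch": res.epoch, "radius_m": zone.radius_m,
               "n_cells": int(ids.size)}
        for label, layer in (("P", res.pressure), ("S", res.state),
                             ("R", res.response), ("ESH", res.esh)):
            vals = layer.values[ids] if ids.size else np.array([])
            vals = vals[np.isfinite(vals)]
            row[label] = float(vals.mean()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def mine_health_counts(mines: np.ndarray, results: list[ESHResult],
                       grid: Grid) -> pd.DataFrame:
    """Tally of mines per health class per epoch.

    Each mine takes the class of the cell containing it; mines on cells with
    missing classification count under "missing".  Counts sum to the number
    of mines every epoch.
    """
    mines = np.asarray(mines, dtype=float).reshape(-1, 2)
    cell_ids = grid.cell_of_points(mines[:, 0], mines[:, 1])
    rows = []
    for res in results:
        if res.health_class is None:
            raise ValueError("health classes not computed; run classify_esh")
        counts = dict.fromkeys(HEALTH_CLASSES + ("missing",), 0)
        for cid in cell_ids:
            cls = res.health_class[cid] if cid >= 0 else -1
            key = HEALTH_CLASSES[cls] if cls >= 0 else "missing"
            counts[key] += 1
        counts["epoch"] = res.epoch
        rows.append(counts)
    return pd.DataFrame(rows).set_index("epoch")
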