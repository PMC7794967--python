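"""Land-use change analysis: transition matrix, dynamic degree, and the
ecological change-direction score.

The change-direction score is a transition-area-weighted mean shift in
ecological level: each converted area contributes the difference between the
destination class's ecological level and the source's, normalised by the
total converted area and expressed in percent.  Positive values mean the
landscape is converting toward ecologically higher-valued cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster

#: per-class ecological levels (dimensionless); built-up carries 0.0 —
#: conversion to construction is treated as the most ecologically negative
#: transition, below even unused land
DEFAULT_ECO_LEVELS = {
    "farmland": 0.11,
    "forestland": 0.245,
    "shrubland": 0.147,
    "high-density grassland": 0.125,
    "mid-density grassland": 0.063,
    "low-density grassland": 0.018,
    "water": 0.282,
    "unused": 0.01,
    "built-up": 0.0,
}


@dataclass
class EcoLevelTable:
    """Ecological level D per land-use class."""

    level: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ECO_LEVELS))

    def __post_init__(self) -> None:
        bad = [k for k, v in self.level.items() if v < 0]
        if bad:
            raise ValueError(f"negative ecological levels for {bad}")

    def __getitem__(self, cls: str) -> float:
        if cls not in self.level:
            raise KeyError(f"class {cls!r} missing from ecological-level table")
        return self.level[cls]


@dataclass
class TransitionMatrix:
    """Class-by-class transition areas (km^2) between two epochs."""

    classes: list[str]
    area: np.ndarray  # area[i][j]: class i at t1 -> class j at t2
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        n = len(self.classes)
        if self.area.shape != (n, n):
            raise ValueError("area matrix shape must match class list")
        if (self.area < 0).any():
            raise ValueError("transition areas must be non-negative")

    def class_area_t1(self, cls: str) -> float:
        return float(self.area[self.classes.index(cls)].sum())

    def class_area_t2(self, cls: str) -> float:
        return float(self.area[:, self.classes.index(cls)].sum())

    def transpose(self) -> "TransitionMatrix":
        return TransitionMatrix(list(self.classes), self.area.T,
                                (self.interval[1], self.interval[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.area, index=self.classes,
                            columns=self.classes)


def transition_matrix(lu_t1: Raster, lu_t2: Raster,
                      interval: tuple[int, int] = (0, 1)) -> TransitionMatrix:
    """Cross-tabulate land-use change between two co-registered rasters.

    Entry (i, j) is the area (km^2) coded class i at t1 and class j at t2;
    pixels that are NoData in either epoch are excluded.
    """
    if not lu_t1.same_registration(lu_t2):
        raise ValueError("rasters do not share grid registration")
    if lu_t1.legend != lu_t2.legend or lu_t1.legend is None:
        raise ValueError("rasters must share a legend")
    valid = lu_t1.valid_mask() & lu_t2.valid_mask()
    codes = np.array(sorted(lu_t1.legend))
    n = len(codes)
    i1 = np.searchsorted(codes, lu_t1.data[valid])
    i2 = np.searchsorted(codes, lu_t2.data[valid])
    counts = np.bincount(i1 * n + i2, minlength=n * n).reshape(n, n)
    pixel_area_km2 = (lu_t1.cell_size / 1000.0) ** 2
    return TransitionMatrix(
        classes=[lu_t1.legend[int(c)] for c in codes],
        area=counts * pixel_area_km2,
        interval=interval,
    )


def lcdm(tm: TransitionMatrix, levels: EcoLevelTable | None = None) -> float:
    """Ecological change-direction score, percent.

    sum over i != j of area[i][j] * (D_j - D_i), divided by the total
    converted (off-diagonal) area, times 100.  Zero when nothing changed.
    """
    levels = levels or EcoLevelTable()
    d = np.array([levels[c] for c in tm.classes])
    off = tm.area.copy()
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    if total == 0:
        return 0.0
    return float((off * (d[None, :] - d[:, None])).sum() / total * 100.0)


def single_dynamic_degree(tm: TransitionMatrix, class_name: str,
                          years: float) -> float:
    """Single land-use dynamic degree, percent per year.

    K = (area_t2 - area_t1) / area_t1 / years * 100.  Undefined (NaN, with a
    warning) when the class had zero area at t1.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if class_name not in tm.classes:
        raise KeyError(f"class {class_name!r} not in transition matrix")
    a1 = tm.class_area_t1(class_name)
    a2 = tm.class_area_t2(class_name)
    if a1 == 0:
        warnings.warn(f"dynamic degree undefined: {class_name!r} has zero "
                      "area at the interval start")
        return float("nan")
    return (a2 - a1) / a1 / years * 100.0
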