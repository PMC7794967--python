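"""Normalisation, weighted pressure-state-response composition, and
natural-breaks health classification.

Indicators are min-max normalised with the pool taken over *all epochs
jointly* (per indicator), so that cross-year statements about the composite
are meaningful; pressure-side indicators carry negative direction, so a
higher subscore always means a healthier state.  The composite health index
is the weight-sum of normalised indicators and equals the sum of the three
layer subscores.  Health classes are cut by Fisher-Jenks natural breaks on
the pooled multi-epoch distribution (one legend for all years).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import IndicatorLayer

HEALTH_CLASSES = ("ill", "unhealthy", "middle", "healthy", "excellent healthy")

#: (indicator, criterion layer, direction, weight) defaults; weights sum to 1
DEFAULT_WEIGHTS = [
    ("pop_density",          "pressure", "negative", 0.11),
    ("interference",         "pressure", "negative", 0.14),
    ("reclamation_rate",     "pressure", "negative", 0.12),
    ("steep_farmland_ratio", "pressure", "negative", 0.05),
    ("vegetation_coverage",  "state",    "positive", 0.11),
    ("shei",                 "state",    "positive", 0.03),
    ("shdi",                 "state",    "positive", 0.03),
    ("contag",               "state",    "positive", 0.03),
    ("resilience",           "state",    "positive", 0.10),
    ("esv",                  "state",    "positive", 0.13),
    ("forest_proportion",    "response", "positive", 0.10),
    ("rds_sensitivity",      "response", "negative", 0.05),
]

LAYERS = ("pressure", "state", "response")


@dataclass(frozen=True)
class WeightEntry:
    indicator: str
    layer: str
    direction: str
    weight: float


@dataclass
class WeightScheme:
    """Indicator weights, criterion-layer membership and directionality."""

    entries: list[WeightEntry] = field(default_factory=lambda: [
        WeightEntry(*row) for row in DEFAULT_WEIGHTS])

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.layer not in LAYERS:
                raise ValueError(f"unknown layer {e.layer!r}")
            if e.direction not in ("positive", "negative"):
                raise ValueError(f"unknown direction {e.direction!r}")
            if e.weight <= 0:
                raise ValueError(f"weight for {e.indicator!r} must be > 0")
        total = sum(e.weight for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")

    def layer_entries(self, layer: str) -> list[WeightEntry]:
        return [e for e in self.entries if e.layer == layer]

    def layer_weight(self, layer: str) -> float:
        return sum(e.weight for e in self.layer_entries(layer))

    def __getitem__(self, indicator: str) -> WeightEntry:
        for e in self.entries:
            if e.indicator == indicator:
                return e
        raise KeyError(indicator)


def normalize(layers: list[IndicatorLayer], direction: str
              ) -> list[IndicatorLayer]:
    """Min-max normalise an indicator across its multi-epoch pool.

    Positive direction: Q = (X - Xmin) / (Xmax - Xmin); negative:
    Q = 1 - (X - Xmin) / (Xmax - Xmin).  Min and max are taken over every
    finite value of every supplied epoch jointly; missing values propagate.
    A constant indicator degenerates to Q = 0.5 everywhere, with a warning.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    pool = np.concatenate([np.ravel(l.values) for l in layers])
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("no finite values to normalise")
    lo, hi = pool.min(), pool.max()
    out = []
    for layer in layers:
        if hi == lo:
            warnings.warn(
                f"indicator {layer.name!r} is constant across the pool; "
                "normalised to 0.5")
            q = np.where(np.isfinite(layer.values), 0.5, np.nan)
        else:
            q = (layer.values - lo) / (hi - lo)
            if direction == "negative":
                q = 1.0 - q
        out.append(layer.with_values(q))
    return out


def layer_subscore(normalized: dict[str, IndicatorLayer],
                   weights: WeightScheme, layer: str) -> IndicatorLayer:
    """Weighted sum of normalised indicators belonging to one criterion layer."""
    entries = weights.layer_entries(layer)
    if not entries:
        raise ValueError(f"no indicators in layer {layer!r}")
    missing = [e.indicator for e in entries if e.indicator not in normalized]
    if missing:
        raise ValueError(f"missing normalised indicators: {missing}")
    ref = normalized[entries[0].indicator]
    total = np.zeros_like(ref.values, dtype=float)
    for e in entries:
        total = total + e.weight * normalized[e.indicator].values
    return ref.with_values(total, name=layer)


def esh(p: IndicatorLayer, s: IndicatorLayer, r: IndicatorLayer
        ) -> IndicatorLayer:
    """Composite health index: the sum of the three layer subscores."""
    return p.with_values(p.values + s.values + r.values, name="esh")


@dataclass
class ESHResult:
    """Per-epoch composite result: subscores, index value, health class."""

    epoch: int | None
    q: dict[str, IndicatorLayer]
    pressure: IndicatorLayer
    state: IndicatorLayer
    response: IndicatorLayer
    esh: IndicatorLayer
    health_class: np.ndarray | None = None  # int codes into HEALTH_CLASSES


def compute_esh(indicator_series: dict[str, list[IndicatorLayer]],
                weights: WeightScheme | None = None) -> list[ESHResult]:
    """Run normalisation and composition for every epoch.

    ``indicator_series`` maps indicator name to its per-epoch layers (all
    epochs, same order for every indicator).
    """
    weights = weights or WeightScheme()
    names = [e.indicator for e in weights.entries]
    missing = [n for n in names if n not in indicator_series]
    if missing:
        raise ValueError(f"missing indicator series: {missing}")
    n_epochs = len(next(iter(indicator_series.values())))
    normalized: dict[str, list[IndicatorLayer]] = {}
    for name in names:
        series = indicator_series[name]
        if len(series) != n_epochs:
            raise ValueError(f"indicator {name!r} has inconsistent epochs")
        normalized[name] = normalize(series, weights[name].direction)
    results = []
    for k in range(n_epochs):
        q = {name: normalized[name][k] for name in names}
        p = layer_subscore(q, weights, "pressure")
        s = layer_subscore(q, weights, "state")
        r = layer_subscore(q, weights, "response")
        results.append(ESHResult(
            epoch=q[names[0]].epoch, q=q, pressure=p, state=s, response=r,
            esh=esh(p, s, r)))
    return results


# --------------------------------------------------------------------------
# Fisher-Jenks natural breaks

def jenks_breaks(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Fisher-Jenks optimal 1-D classification into ``k`` classes.

    Returns the k-1 break points, each the largest value of its lower class,
    so membership with "boundary values go to the lower class" is
    ``searchsorted(breaks, v, side='left')``.  Minimises the within-class sum
    of squared deviations over all contiguous partitions (dynamic program,
    exact).  If fewer than k distinct finite values exist, k is reduced with
    a warning.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = np.sort(v[np.isfinite(v)])
    n = v.size
    if n == 0:
        raise ValueError("no finite values")
    n_distinct = np.unique(v).size
    if n_distinct < k:
        warnings.warn(f"only {n_distinct} distinct values; reducing classes "
                      f"from {k} to {n_distinct}")
        k = n_distinct
    if k <= 1:
        return np.array([])
    # prefix sums for O(1) within-segment SSD
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        """SSD of segment v[i..j] inclusive, vectorised over i."""
        cnt = j - i + 1
        s = c1[j + 1] - c1[i]
        ss = c2[j + 1] - c2[i]
        return ss - s * s / cnt

    # dp[c, j]: optimal cost of partitioning v[0..j] into c+1 classes
    dp = np.empty((k, n))
    arg = np.zeros((k, n), dtype=np.int64)
    idx = np.arange(n)
    cnt = np.arange(1, n + 1, dtype=float)
    dp[0] = c2[1:] - c1[1:] ** 2 / cnt  # one class covering v[0..j]
    for c in range(1, k):
        for j in range(n):
            if j < c:
                dp[c, j] = 0.0
                arg[c, j] = j
                continue
            starts = idx[c:j + 1]  # first index of the last class
            cost = dp[c - 1, starts - 1] + seg_cost(starts, j)
            best = int(np.argmin(cost))
            dp[c, j] = cost[best]
            arg[c, j] = starts[best]
    # recover break values (last element of each lower class)
    breaks = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        start = arg[c, j]
        breaks.append(v[start - 1])
        j = start - 1
    return np.array(breaks[::-1])


def classify(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Class index per value given break points; -1 marks missing.

    Values equal to a break fall in the lower class.  With k-1 breaks the
    classes run 0..k-1 (for the 5-level health legend, 0 = "ill",
    4 = "excellent healthy").
    """
    v = np.asarray(values, dtype=float)
    cls = np.searchsorted(np.asarray(breaks), v, side="left")
    return np.where(np.isfinite(v), cls, -1).astype(np.int64)


def classify_esh(results: list[ESHResult], k: int = 5) -> np.ndarray:
    """Cut health classes on the pooled multi-epoch composite distribution.

    Fills each result's ``health_class`` in place and returns the breaks.
    """
    pool = np.concatenate([r.esh.values for r in results])
    breaks = jenks_breaks(pool, k)
    for r in results:
        r.health_class = classify(r.esh.values, breaks)
    return breaks
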