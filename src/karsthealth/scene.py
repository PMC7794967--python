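"""Synthetic study-scene generator.

Emulates the data a grid-based ecosystem-health assessment of a karst mining
city consumes: a categorical land-use series on a 1 km raster, a DEM,
population-density and per-capita-GDP surfaces, mine points clustered in
mining belts, and a carbonate (karst lithology) mask — with the statistical
structure the downstream analysis assumes (patchy land cover, Markov
land-use change with urban expansion around seeded centers and post-2000
farmland-to-forest/grassland conversion, economic surfaces decaying from
urban centers and growing over time).

Everything is deterministic for a fixed scene seed; per-stage child seeds
are derived from it so stages are reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import INT_NODATA, LANDUSE_LEGEND, Raster

N_CLASSES = len(LANDUSE_LEGEND)  # codes 1..9
_CODE = {name: code for code, name in LANDUSE_LEGEND.items()}

#: initial class mixture (probability a patch nucleus takes each class)
DEFAULT_CLASS_MIX = {
    "farmland": 0.30,
    "forestland": 0.20,
    "shrubland": 0.07,
    "high-density grassland": 0.10,
    "mid-density grassland": 0.12,
    "low-density grassland": 0.08,
    "water": 0.02,
    "unused": 0.04,
    "built-up": 0.07,
}


def identity_regime() -> np.ndarray:
    return np.eye(N_CLASSES)


def default_regimes(epochs: list[int]) -> list[np.ndarray]:
    """One transition matrix per epoch interval.

    Pre-2000 intervals: mild agricultural expansion (grassland to farmland)
    plus slow urbanization.  Post-2000 intervals additionally convert
    farmland to forest and grassland (grain-for-green-style restoration).
    Built-up land is absorbing, so its area never decreases.
    """
    regimes = []
    for t0 in epochs[:-1]:
        m = identity_regime().copy()

        def move(src: str, dst: str, p: float) -> None:
            i, j = _CODE[src] - 1, _CODE[dst] - 1
            m[i, i] -= p
            m[i, j] += p

        # slow background urbanization of farmland/grassland (boosted near
        # urban centers at generation time)
        for src in ("farmland", "mid-density grassland", "low-density grassland"):
            move(src, "built-up", 0.004)
        if t0 < 2000:
            move("high-density grassland", "farmland", 0.02)
            move("mid-density grassland", "farmland", 0.02)
            move("forestland", "farmland", 0.005)
        else:
            move("farmland", "forestland", 0.03)
            move("farmland", "high-density grassland", 0.02)
            move("low-density grassland", "mid-density grassland", 0.02)
        regimes.append(m)
    return regimes


@dataclass
class SceneParams:
    """Parameters of the synthetic scene.

    The defaults describe a 60 km x 60 km landscape observed at 1 km
    resolution over six epochs, with 66 mines in two mining belts — a
    scaled-down analogue of a karst prefecture dominated by coal mining.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 60_000.0, 60_000.0)
    cell_size_m: float = 1000.0
    epochs: list[int] = field(
        default_factory=lambda: [1990, 1995, 2000, 2005, 2010, 2015])
    n_urban_centers: int = 3
    n_mines: int = 66
    transition_regimes: list[np.ndarray] | None = None
    relief_amplitude_m: float = 1500.0
    carbonate_fraction: float = 0.6318
    #: per-interval multiplicative growth of POP and GDP surfaces
    pop_growth: float = 1.15
    gdp_growth: float = 1.35
    #: extra probability mass moved into built-up at an urban-center pixel
    urban_boost: float = 0.25
    #: e-folding scale of the urban-expansion kernel, metres
    urban_kernel_m: float = 6000.0
    #: mining belts as (x_min, y_min, x_max, y_max) rectangles; None = derived
    mining_belts: list[tuple[float, float, float, float]] | None = None
    n_patch_nuclei: int = 220
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ValueError("epochs must be strictly increasing")
        if self.n_urban_centers < 1:
            raise ValueError("need at least one urban center")
        if self.n_mines < 0:
            raise ValueError("n_mines must be >= 0")
        if self.transition_regimes is None:
            self.transition_regimes = default_regimes(self.epochs)
        if len(self.transition_regimes) != len(self.epochs) - 1:
            raise ValueError("need one transition regime per epoch interval")
        for k, m in enumerate(self.transition_regimes):
            m = np.asarray(m, dtype=float)
            self.transition_regimes[k] = m
            if m.shape != (N_CLASSES, N_CLASSES) or (m < -1e-12).any():
                raise ValueError(f"regime {k} is not a {N_CLASSES}x{N_CLASSES} "
                                 "non-negative matrix")
            bad = np.where(np.abs(m.sum(axis=1) - 1.0) > 1e-9)[0]
            if bad.size:
                names = [LANDUSE_LEGEND[i + 1] for i in bad]
                raise ValueError(
                    f"regime {k}: rows for {names} do not sum to 1")

    def _rng(self, stage: str) -> np.random.Generator:
        # stable across processes (unlike hash()) so scenes are reproducible
        key = zlib.crc32(stage.encode())
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    @property
    def grid_shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.extent
        return (int(round((y1 - y0) / self.cell_size_m)),
                int(round((x1 - x0) / self.cell_size_m)))

    def default_belts(self) -> list[tuple[float, float, float, float]]:
        """Two horizontal mining belts in the southern half of the scene."""
        x0, y0, x1, y1 = self.extent
        w, h = x1 - x0, y1 - y0
        return [
            (x0 + 0.10 * w, y0 + 0.15 * h, x0 + 0.55 * w, y0 + 0.35 * h),
            (x0 + 0.50 * w, y0 + 0.40 * h, x0 + 0.90 * w, y0 + 0.60 * h),
        ]


@dataclass
class SyntheticScene:
    params: SceneParams
    landuse_series: list[Raster]
    dem: Raster
    pop_series: list[Raster]
    gdp_series: list[Raster]
    mines: np.ndarray
    carbonate_mask: Raster
    urban_centers: np.ndarray


def _raster(params: SceneParams, data: np.ndarray, *, categorical: bool
            ) -> Raster:
    x0, _, _, y1 = params.extent
    return Raster(
        data=data,
        x_origin=x0,
        y_origin=y1,
        cell_size=params.cell_size_m,
        nodata=INT_NODATA if categorical else -9999.0,
        legend=LANDUSE_LEGEND if categorical else None,
    )


def _urban_centers(params: SceneParams) -> np.ndarray:
    rng = params._rng("urban-centers")
    x0, y0, x1, y1 = params.extent
    margin = 0.15
    xs = rng.uniform(x0 + margin * (x1 - x0), x1 - margin * (x1 - x0),
                     params.n_urban_centers)
    ys = rng.uniform(y0 + margin * (y1 - y0), y1 - margin * (y1 - y0),
                     params.n_urban_centers)
    return np.column_stack([xs, ys])


def _urban_kernel(params: SceneParams, centers: np.ndarray) -> np.ndarray:
    """Per-pixel Gaussian proximity to the nearest urban center, in [0, 1]."""
    template = _raster(params, np.zeros(params.grid_shape), categorical=False)
    xs, ys = template.pixel_centers()
    k = np.zeros(params.grid_shape)
    for cx, cy in centers:
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        k = np.maximum(k, np.exp(-d2 / (2 * params.urban_kernel_m ** 2)))
    return k


def _initial_landscape(params: SceneParams) -> np.ndarray:
    """Patchy categorical start: nearest-nucleus assignment + majority filter."""
    rng = params._rng("initial-landscape")
    n_rows, n_cols = params.grid_shape
    x0, y0, x1, y1 = params.extent
    names = list(params.class_mix)
    probs = np.array([params.class_mix[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    nx = rng.uniform(x0, x1, params.n_patch_nuclei)
    ny = rng.uniform(y0, y1, params.n_patch_nuclei)
    ncls = rng.choice([_CODE[n] for n in names], size=params.n_patch_nuclei,
                      p=probs)
    template = _raster(params, np.zeros((n_rows, n_cols)), categorical=False)
    xs, ys = template.pixel_centers()
    # nearest nucleus (Voronoi patches)
    best = np.full((n_rows, n_cols), np.inf)
    codes = np.zeros((n_rows, n_cols), dtype=np.int64)
    for px, py, pc in zip(nx, ny, ncls):
        d2 = (xs - px) ** 2 + (ys - py) ** 2
        closer = d2 < best
        best[closer] = d2[closer]
        codes[closer] = pc
    # 3x3 majority filter to knock out slivers while keeping patch structure
    onehot = np.stack([(codes == c).astype(float)
                       for c in range(1, N_CLASSES + 1)])
    smoothed = np.stack([
        ndimage.uniform_filter(layer, size=3, mode="nearest")
        for layer in onehot])
    return np.argmax(smoothed, axis=0).astype(np.int64) + 1


def generate_landuse_series(params: SceneParams) -> list[Raster]:
    """Generate one categorical land-use raster per epoch.

    Epoch 0 is a spatially clustered landscape; each later epoch applies the
    interval's Markov regime cell-wise, with the probability of conversion to
    built-up boosted within a Gaussian kernel of the urban centers (mass taken
    from the probability of staying put).
    """
    centers = _urban_centers(params)
    kernel = _urban_kernel(params, centers)
    codes = _initial_landscape(params)
    rng = params._rng("landuse-transitions")
    built = _CODE["built-up"] - 1
    series = [codes]
    for regime in params.transition_regimes:
        prev = series[-1]
        flat = prev.ravel() - 1
        prob = regime[flat]  # (n_pixels, n_classes)
        # urban-expansion boost near centers, taken from the diagonal mass
        boost = (params.urban_boost * kernel.ravel()
                 * (flat != built) * prob[np.arange(flat.size), flat])
        prob = prob.copy()
        prob[np.arange(flat.size), flat] -= boost
        prob[:, built] += boost
        cum = np.cumsum(prob, axis=1)
        u = rng.random(flat.size)
        new = (u[:, None] < cum).argmax(axis=1) + 1
        series.append(new.reshape(prev.shape).astype(np.int64))
    return [_raster(params, s, categorical=True) for s in series]


def generate_surfaces(landuse_series: list[Raster], params: SceneParams
                      ) -> tuple[Raster, list[Raster], list[Raster], Raster]:
    """DEM, POP and GDP series, and carbonate mask on the land-use grid.

    The DEM is multi-scale smoothed noise scaled to ``relief_amplitude_m``.
    POP and GDP are sums of Gaussian kernels on the urban centers plus a low
    background, multiplied by a per-interval growth factor so scene totals
    increase monotonically across epochs.  The carbonate mask thresholds a
    smooth field at the quantile matching ``carbonate_fraction``.
    """
    shape = params.grid_shape
    rng = params._rng("surfaces")
    # DEM: sum of white noise smoothed at three scales
    noise = rng.standard_normal(shape)
    dem = np.zeros(shape)
    # multi-scale roughness: the fine component gives karst terrain its
    # pixel-to-pixel relief, the coarse ones the ridge-and-valley fabric
    for sigma, w in ((1, 0.35), (3, 0.5), (8, 0.8), (15, 1.0)):
        layer = ndimage.gaussian_filter(noise, sigma, mode="nearest")
        dem += w * layer / max(layer.std(), 1e-12)
    span = dem.max() - dem.min()
    if span > 0 and params.relief_amplitude_m > 0:
        dem = (dem - dem.min()) / span * params.relief_amplitude_m
        # carve river gorges: narrow canyons whose walls are the only
        # terrain steep enough (>25 deg at 1 km) to carry sloping farmland,
        # as in real karst plateaus dissected by deep river valleys
        n_rows, n_cols = shape
        gorge = np.zeros(shape, dtype=bool)
        for _ in range(max(2, n_cols // 20)):
            r = float(rng.integers(n_rows // 8, n_rows - n_rows // 8))
            for c in range(n_cols):
                gorge[int(np.clip(r, 0, n_rows - 1)), c] = True
                r += rng.choice([-1, 0, 1])
        dist = ndimage.distance_transform_edt(~gorge)
        dem = dem - 0.8 * params.relief_amplitude_m * np.exp(-(dist / 0.9) ** 2)
        dem = dem - dem.min() + 600.0
    else:
        dem = np.full(shape, 1400.0)
    dem_raster = _raster(params, dem, categorical=False)

    centers = _urban_centers(params)
    kernel = np.zeros(shape)
    xs, ys = dem_raster.pixel_centers()
    for cx, cy in centers:
        d2 = (xs - cx) ** 2 + (cy - ys) ** 2
        kernel += np.exp(-d2 / (2 * (0.6 * params.urban_kernel_m) ** 2))
    pop0 = 2000.0 * kernel + 40.0
    gdp0 = 9000.0 * kernel + 800.0
    pop_series, gdp_series = [], []
    for k, _epoch in enumerate(params.epochs):
        pop_series.append(_raster(params, pop0 * params.pop_growth ** k,
                                  categorical=False))
        gdp_series.append(_raster(params, gdp0 * params.gdp_growth ** k,
                                  categorical=False))

    carb_field = ndimage.gaussian_filter(rng.standard_normal(shape), 8,
                                         mode="nearest")
    if params.carbonate_fraction <= 0:
        mask = np.zeros(shape, dtype=np.int64)
    elif params.carbonate_fraction >= 1:
        mask = np.ones(shape, dtype=np.int64)
    else:
        thr = np.quantile(carb_field, 1.0 - params.carbonate_fraction)
        mask = (carb_field >= thr).astype(np.int64)
    carbonate = Raster(mask, dem_raster.x_origin, dem_raster.y_origin,
                       params.cell_size_m, nodata=-1)
    return dem_raster, pop_series, gdp_series, carbonate


def generate_mines(landuse_series: list[Raster], params: SceneParams
                   ) -> np.ndarray:
    """Sample ``n_mines`` point locations inside the mining belts."""
    belts = params.mining_belts or params.default_belts()
    x0, y0, x1, y1 = params.extent
    for b in belts:
        if not (x0 <= b[0] < b[2] <= x1 and y0 <= b[1] < b[3] <= y1):
            raise ValueError(f"mining belt {b} outside scene extent")
    if params.n_mines == 0:
        return np.empty((0, 2))
    rng = params._rng("mines")
    areas = np.array([(b[2] - b[0]) * (b[3] - b[1]) for b in belts])
    belt_idx = rng.choice(len(belts), size=params.n_mines,
                          p=areas / areas.sum())
    pts = np.empty((params.n_mines, 2))
    for i, bi in enumerate(belt_idx):
        bx0, by0, bx1, by1 = belts[bi]
        pts[i] = (rng.uniform(bx0, bx1), rng.uniform(by0, by1))
    return pts


def generate_scene(params: SceneParams | None = None) -> SyntheticScene:
    """Generate the full synthetic scene for the given parameters."""
    params = params or SceneParams()
    landuse = generate_landuse_series(params)
    dem, pop, gdp, carbonate = generate_surfaces(landuse, params)
    mines = generate_mines(landuse, params)
    return SyntheticScene(
        params=params,
        landuse_series=landuse,
        dem=dem,
        pop_series=pop,
        gdp_series=gdp,
        mines=mines,
        carbonate_mask=carbonate,
        urban_centers=_urban_centers(params),
    )


def coupled_preset(seed: int = 0) -> SceneParams:
    """Preset in which urbanization and mining deliberately overlap.

    The mining belts are drawn around the urban centers, so mines sit on
    interference-heavy terrain and the urbanization surface peaks where
    ecosystem condition is most degraded — the configuration under which the
    downstream urbanization-vs-health association is expected to be negative.
    """
    params = SceneParams(seed=seed, urban_boost=0.45)
    centers = _urban_centers(params)
    x0, y0, x1, y1 = params.extent
    belts = []
    half = 6000.0
    for cx, cy in centers:
        belts.append((
            max(x0, cx - half), max(y0, cy - half),
            min(x1, cx + half), min(y1, cy + half),
        ))
    params.mining_belts = belts
    return params
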