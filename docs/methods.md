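# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `karsthealth`, and what the synthetic tests do and
do not establish about real data.

## Assessment model

The assessment unit is a 2 km × 2 km fishnet cell; input rasters are
nominally 1 km, so four pixels nest in each cell. Raster pixels are
assigned to the unique cell containing their center (half-open cell
intervals `[x, x+s) × (y−s, y]`), which is exact for nested grids and
unambiguous for misaligned ones; no pixel is double-counted or dropped.
Cells with no valid pixels are *missing* and stay missing through
normalisation, classification, spatial weights and zonal means.

**Indicators.** Twelve indicators in three criterion layers (defaults, with
direction in parentheses; weights sum to 1):

| layer | indicator | weight |
|---|---|---|
| pressure | population density (−) | 0.11 |
| pressure | man-made interference (−) | 0.14 |
| pressure | land reclamation rate (−) | 0.12 |
| pressure | steep-farmland proportion (−) | 0.05 |
| state | vegetation coverage (+) | 0.11 |
| state | Shannon evenness (+) | 0.03 |
| state | Shannon diversity (+) | 0.03 |
| state | contagion (+) | 0.03 |
| state | ecological resilience (+) | 0.10 |
| state | ecosystem-service value (+) | 0.13 |
| response | forest proportion (+) | 0.10 |
| response | rocky-desertification sensitivity (−) | 0.05 |

Pressure indicators carry negative direction so a *higher* pressure
subscore means *less* pressure; the composite is monotone increasing in
ecosystem condition everywhere.

Man-made interference, resilience and ecosystem-service value share one
construction — an area-weighted sum of per-class coefficients over the
cell's land-cover mix — with three separate coefficient tables
(hemeroby-style interference: built-up 1.0 … water 0.05; resilience:
forest 1.0 … built-up 0.05; service value following the common Chinese
equivalent-value pattern: water highest, forest high, built-up 0). The
tables live in configuration (`config.load_coefficient_table`), not code.
Vegetation coverage is the vegetated-class area fraction — a land-cover
proxy, not a reflectance-based index.

Landscape metrics (SHDI, SHEI, CONTAG) treat each 2 km cell as one
landscape. CONTAG uses 4-neighbour adjacency with double counting.  Note a
formula property worth knowing: for two classes a perfect checkerboard
concentrates all adjacency off-diagonal and scores exactly 50 — it is *not*
the minimum; the minimum (→ 0) needs a uniform adjacency mix across ≥ 3
classes. A single-class or single-pixel cell scores 100 by definition.

Rocky-desertification sensitivity is a banded rule: carbonate area fraction
× (slope-band score at the cell-mean slope + coverage-band score at the
cell's vegetation coverage), rescaled by the maximum attainable sum to
[0, 1]. Default bands: slope < 5/5–15/15–25/> 25° scoring 1–4; coverage
< 0.3/0.3–0.5/0.5–0.7/> 0.7 scoring 4–1. Slope comes from Horn's 3×3
estimator (the common GIS default) with edge replication.

The steep-farmland denominator is *all* pixels in the cell, so cells
without farmland score zero pressure rather than missing.

**Normalisation and classification.** Min–max normalisation pools every
epoch jointly per indicator, so cross-year differences in subscores are
meaningful; a per-epoch pool is available as an option. A constant
indicator normalises to 0.5 with a warning rather than failing, keeping a
degenerate layer neutral. Health classes come from exact Fisher–Jenks
dynamic programming on the pooled multi-epoch composite (one legend for all
years); boundary values join the lower class; when fewer distinct values
than classes exist, the class count is reduced with a warning.

**Spatial association.** Weights default to queen contiguity on the
fishnet, row-standardised (rook and k-nearest available). Missing cells are
dropped *before* neighbour construction; islands created by the removal
keep empty weight rows. Bivariate Moran's I uses population-sd z-scores:
I = z_xᵀ W z_y / n. The permutation test permutes y over locations with x
and W fixed; the reported pseudo-p is one-sided in the direction of the
observed sign with the (extreme + 1)/(permutations + 1) correction, so
0.001 is the floor at 999 permutations. **Calibration caveat:** because
that convention picks its tail after seeing the sign, its null rejection
rate at nominal level α is ≈ 2α; `MoranResult.pseudo_p_two_sided` (the
directional p doubled, capped at 1) is the validly calibrated quantity and
is what the calibration tests check. z-values are taken against the
permutation distribution (the analytic approximation is not used). Local
statistics use conditional permutation — each cell's neighbour values
resampled without replacement from all other cells — and the cluster class
comes from the signs of z_x and the spatial lag of z_y, masked at the
chosen α.

**Mine zones.** Buffers are dissolved per radius (2/3/6 km defaults; the
2 km zone is the headline, having the least overlap between mines); cell
membership is by cell-center containment, consistent with the pixel-center
rule. Zonal means are unweighted over member cells, so mean ESH equals the
sum of the mean subscores exactly. Each mine takes the health class of the
cell containing it.

**Change-direction score.** The denominator is the *changed* (off-diagonal)
area only; including unchanged area would make scores incommensurable
between intervals of different stability. Built-up land, absent from the
ecological-level table, defaults to level 0.0 — below unused land —
because conversion to construction is the most degrading transition in this
setting; the level table is configurable. The dynamic-degree formula is the
standard K = (U_b − U_a)/(U_a T) × 100 %.

## Synthetic scene generator

The generator emulates the statistical structure of the data the assessment
consumes; its defaults describe a 60 km × 60 km landscape at 1 km
resolution over epochs 1990–2015 (five-year steps) — a deliberately
scaled-down analogue of a ~10 000 km² prefecture, sized so the full
pipeline and its Monte-Carlo tests run in seconds.

- **Initial land cover:** ~220 class-typed nuclei, nearest-nucleus (Voronoi)
  assignment, one 3×3 majority-filter pass — patchy, spatially
  autocorrelated cover, which the landscape metrics require (i.i.d. noise
  would make CONTAG/SHDI meaningless). The class mix is roughly farmland
  0.30 / forest 0.20 / grassland 0.30 / built-up 0.07 / rest water, shrub,
  unused.
- **Change:** cell-wise Markov transitions per epoch interval. Pre-2000
  regimes expand agriculture (grassland→farmland) with slow urbanization;
  post-2000 regimes convert farmland to forest and grassland
  (grain-for-green-style restoration). Conversion to built-up gains extra
  probability (default 0.25, taken from the stay-put mass) inside a 6 km
  Gaussian kernel of the seeded urban centers; built-up is absorbing, so
  its area never decreases.
- **Terrain:** multi-scale Gaussian roughness scaled to a 1500 m relief,
  plus a few random-walk river gorges cut ~0.8 × relief deep and ~1 px
  wide. The gorges matter: smooth Gaussian fields at 1 km resolution cannot
  produce the > 25° slopes karst canyons actually have, and without them
  the steep-farmland indicator would be degenerate (typical result: mean
  slope ≈ 5°, ~1–3 % of pixels > 25°).
- **POP/GDP:** Gaussian kernels on the urban centers plus a low background,
  grown multiplicatively per interval (defaults ×1.15 and ×1.35 per 5-year
  step), so totals rise monotonically.
- **Carbonate mask:** a smoothed field thresholded at the quantile matching
  the configured karst fraction (default 0.6318).
- **Mines:** 66 points by default, area-weighted uniform over configurable
  mining-belt rectangles. The *coupled* preset centres the belts on the
  urban centers and raises the urban boost, deliberately overlapping
  mining, urbanization and degraded terrain — the configuration under which
  the urbanization–health association is expected to be negative and mine
  zones less healthy than the scene mean.
- **Determinism:** one scene seed; per-stage child seeds derived via a
  CRC-keyed `SeedSequence`, so every stage is bit-reproducible in isolation
  and across processes.

What the generator does *not* emulate: real geography or class areas,
subpixel mixing, classification error in land-use maps, NDVI phenology,
migration-driven population redistribution, or any calibration of
transition magnitudes to observed change statistics. Passing tests
therefore establish the correctness and internal coherence of the
*computations* under realistic structure — not the empirical values any
particular real region would produce.

## Problem sizes and numerical choices

- Default scene: 3 600 pixels, 900 fishnet cells, 6 epochs; the full
  pipeline with 999-permutation global and local tests runs in a few
  seconds. Unit tests use 10–20 km scenes; the null-calibration check uses
  a 15×15 cell grid with 500 replicates of the 999-permutation test.
- Fisher–Jenks is the exact O(k·n²) dynamic program (n = pooled cell-epoch
  values, ~5 400 at default size); verified against exhaustive partition
  enumeration for n ≤ 12.
- The LISA conditional permutation draws neighbour sets by rejection
  sampling on duplicate rows — efficient because neighbourhoods (≤ 8) are
  tiny relative to the cell count.
- Zonal fractions/means use exact integer bincounts over pixel-center cell
  ids; buffer disks are polygonised with 64 quadrant segments (area error
  < 0.1 %).
- Degenerate inputs: single-pixel DEM → zero slope; empty transition → 0 %
  change score; class with zero initial area → dynamic degree missing with
  a warning; zone without cell centers → missing statistics with a warning.

## Known limitations

- No on-the-fly reprojection: all inputs must share one projected CRS.
- Raster I/O is ESRI ASCII grid (plus a JSON legend sidecar); continuous
  NoData −9999, categorical NoData 0.
- The interference/resilience/service-value coefficient tables and the
  rocky-desertification rule are literature-style defaults, not fitted
  quantities; any real-region application should review them.
- The weight scheme is a fixed input; the package does not implement the
  pairwise-comparison elicitation that would produce alternative weights.
- Landscape metrics on 2×2-pixel cells are coarse by construction; a finer
  input raster (the cell/pixel ratio is free) sharpens them.
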