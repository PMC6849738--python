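# Methods

`woodytrends` implements a regional woody-vegetation change analysis of the
kind used to map forest loss and gain across the tropical and subtropical
Andes from annual MODIS-derived land-cover maps, together with a fully
truth-labeled synthetic study region so that every stage can be validated
without satellite downloads.

## The analysis chain

1. **Composite series.** Each 250 m pixel contributes 23 sixteen-day
   composites per year (EVI plus blue, red, NIR, MIR reflectance) with a
   pixel-reliability code per observation. Observations with reliability
   code 3 (unreliable: cloud, snow) are removed before anything else is
   computed.
2. **Temporal features.** For every variable and every window of the year —
   the full 12 months, two 6-month halves, three 4-month thirds — the mean,
   sample standard deviation (n−1 denominator), minimum, maximum and range
   of the reliable observations: 5 × 6 × 5 = 150 predictors per pixel-year.
   Composites join windows by their start day-of-year; halves split at day
   182, thirds at days 121 and 243 (the product's 16-day start dates are
   1, 17, …, 353). An alternative reading of the window set (12 calendar
   months plus halves and thirds) is selectable but not the default; the
   default matches the 1 + 2 + 3 window enumeration. A window emptied by
   the reliability screen inherits the 12-month statistic; a pixel-year with
   no reliable observation at all is unusable and maps to the "other" class.
3. **Classification.** One Random Forest per mapping zone (zones follow the
   biome layers), trained on labeled pixels paired with the feature vector
   of their reference year, applied to all 14 years independently — no
   temporal smoothing or post-filtering. Classes: cropland,
   pasture/grassland, woody (natural trees and shrubs), plantation, other.
   The woody mask used downstream excludes plantation by default
   (`include_plantation` switches this for sensitivity analysis).
4. **Hexagon accounting.** A regular hexagon grid (flat edges facing
   north/south, flat-to-flat width 11.547 km, area (√3/2)·w² = 115.47 km²)
   tiles the region. A hexagon enters the study set when its median DEM
   elevation is ≥ 1,000 m and it intersects at least one study biome.
   Pixel membership is by pixel center, computed as nearest lattice center,
   which for a regular hexagonal tessellation is identical to
   point-in-polygon; exact boundary ties resolve to the lexicographically
   smallest cell id. Per hexagon and year, woody area = woody-pixel count ×
   6.25 ha.
5. **Trend filter.** Each hexagon's 14-value area series is regressed on
   calendar year by OLS; the two-sided t test on the slope (df = 12) at
   α = 0.05 labels the hexagon gain, loss, or no trend. Net change for a
   significant hexagon is the observed endpoint difference
   area(2014) − area(2001) (a fitted-endpoint option exists). No
   multiple-testing correction is applied by default, matching the
   reference procedure; Benjamini–Hochberg is available as a switch.
   Gains and losses are summed within seven 500 m elevation zones
   (half-open bins from 1,000 m, the last open above 4,000 m) and within
   countries (hexagons are assigned to the country of largest overlap).
6. **Drivers.** For significant hexagons, gain (1) vs loss (0) is modeled
   by logistic regression on country, elevation class (the 7-level zone
   factor), mean Horn-method slope (degrees), ΔNTL and Δrural population
   (2001–2011, municipality values allocated to hexagons by area weighting).
   All 2⁵ = 32 main-effect subsets are fitted and ranked by
   AIC = −2logL + 2k; Akaike weights are normalized over the full fitted
   set (not a confidence subset). Categorical terms are dummy-coded against
   the alphabetically first level. Perfectly separated fits are flagged and
   excluded from the ranking.

## The synthetic study region

The generator emulates the inputs of the real analysis in a planar
equal-area world (meters; areas, not positions, drive every statistic, so
no reprojection machinery is needed).

- **Phenology.** Per class, EVI follows a sinusoid
  level + amplitude·sin(2πd/365 + phase); cropland gets a second harmonic
  to mimic double cropping. Defaults: woody 0.58/0.08, plantation
  0.52/0.10, pasture 0.42/0.18, cropland 0.35/0.25, other 0.12/0.03.
  Reflectance bands are flat class means plus noise.
- **Noise structure.** The real product's noise structure is not published,
  so three scales are exposed in configuration and set to realistic EVI
  variability: a per-pixel site effect (SD 0.05 on level, 0.05 on
  amplitude), a per-pixel-year interannual anomaly (SD 0.03 — droughts and
  fires make real composite series fluctuate between years, which is what
  makes annual maps flicker at class boundaries), and per-observation noise
  (SD 0.04 for EVI, 0.02 for bands). EVI is clipped to [−0.2, 1].
  Reliability codes are i.i.d. {0 good, 3 unreliable} with dropout
  probability 0.05; only code 3 is ever acted on.
- **Landscape and layers.** Initial classes form spatially coherent patches
  (quantile-thresholded smoothed Gaussian field; default cover 40% woody,
  30% pasture, 15% cropland, 5% plantation, 10% other). The DEM is a
  south-to-north ramp (base 900 m, relief 2,600 m) plus smoothed noise, so
  elevation zones and the ≥ 1,000 m filter are both exercised. Countries
  and municipalities are Voronoi tessellations of seeded points; biomes are
  elevation bands of the mean profile. Scripted transitions convert a fixed
  seeded quota of a region's source-class pixels each year, producing
  exactly linear hexagon-level trends (within one pixel of rounding) whose
  truth is recorded per pixel-year and per hexagon.
- **Drivers.** Municipalities containing scripted abandonment (conversion
  into woody from pasture/cropland) receive negative Δrural-population
  proportional to the abandoned fraction plus Gaussian noise; ΔNTL
  likewise with its own effect size. A record-level simulator draws
  significant-hexagon covariates and outcomes from an explicit logistic
  generating model (treatment-coded, Δpopulation coefficient negative by
  default) for parameter-recovery checks.

### What the generator does not emulate

Radiative-transfer realism, spatially correlated cloud fields, orbital
geometry, and the area variation of real sinusoidal-projection pixels are
out of scope. Classification accuracy on this synthetic world (typically
97–98% woody/non-woody) is a sanity bound, not an estimate of accuracy on
real imagery; passing tests show the machinery is correct, not that real
Andean land cover would be mapped this well.

## Problem sizes and numerical choices

- Validation simulations are scaled to desk size as the package's own
  design choice: the trend-filter calibration uses a 600 × 600-pixel null
  world tiled into ~2,000 hexagons of ~200 pixels each. The hexagon width
  is scaled so each cell still holds enough pixels that a completely
  flip-free (constant) series is rare — full-size cells hold 1,847 pixels
  and never produce one; with fewer than ~100 pixels per cell, constant
  series deflate the measured type-I fraction below α. The power check
  scripts a conversion of ≥ 2 pixels/yr per hexagon on a 300 × 300 world;
  classifier sanity runs on the 120 × 120 default world.
- Zero-variance area series have no defined trend and are reported as
  direction "none" with p = NaN.
- SD of a single observation is undefined (NaN) and imputed from the
  12-month window like any other missing window statistic.
- Degenerate inputs fail loudly: grids too small for one hexagon,
  single-row DEMs, empty reference sets, single-class training zones.
- One master seed derives per-stage seeds; reruns are byte-identical,
  including the Random Forest (fixed `random_state`, `n_jobs=1`).

## Known limitations

- The hexagon grid orientation of the original analysis is not recoverable
  from its description; flat-north/south (north–south extent = flat-to-flat
  width) is implemented and all summaries are orientation-invariant.
- Whether plantation counted as woody in the original hexagon sums is
  ambiguous; the default excludes it.
- Spatial autocorrelation among neighboring hexagons is not modeled or
  corrected for, matching the reference procedure.
- The driver analysis is main-effects-only over five predictors; no
  interactions, no mixed models.
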