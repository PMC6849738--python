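# woodytrends

Hexagon-grid trend analysis of woody-vegetation change in tropical mountain
regions, built around the workflow used to map forest loss and gain across
the Andes from annual MODIS-derived land-cover maps — plus a fully
truth-labeled synthetic study region so the entire chain is testable on a
laptop, without satellite downloads.

**Who it is for.** Landscape ecologists and remote-sensing analysts who want
a tested, reproducible implementation of the
classify → tessellate → trend-filter → account → drivers pipeline, and
method developers who need a ground-truthed test bed for evaluating change
detection along elevation gradients.

## The method

Each 250 m pixel-year contributes 23 sixteen-day composites (EVI, blue,
red, NIR, MIR, pixel reliability). After removing unreliable observations
(reliability code 3), the mean, SD, min, max and range of each variable are
computed over the full year, two half-year and three third-year windows
(150 features). Zone-specific Random Forests produce 14 annual land-cover
maps (cropland, pasture/grassland, woody, plantation, other).

A regular hexagon tessellation (flat-to-flat width *w* = 11.547 km; area
(√3/2)·w² = 115.47 km² ≈ 11,547 ha) is laid over the maps; hexagons with
median elevation ≥ 1,000 m intersecting the study biomes form the study
set. Per hexagon, the annual woody area *A(t)* (ha) is regressed on year:

&nbsp;&nbsp;&nbsp;&nbsp;*A(t) = β₀ + β₁ t + ε*,&nbsp;&nbsp; t = 2001, …, 2014

and a two-sided t test on *β₁* (df = 12, α = 0.05) classifies the hexagon
as significant gain (*β₁* > 0), loss (*β₁* < 0) or no trend. Net change
for significant hexagons, *A(2014) − A(2001)*, is summed within seven
500 m elevation zones and by country. Finally, gain (1) vs loss (0) is
related to country, elevation class, mean slope (Horn's method), ΔNTL and
Δrural population by exhaustive logistic model selection: all 2⁵ = 32
main-effect subsets ranked by AIC with Akaike weights
*wᵢ = exp(−ΔAICᵢ/2) / Σⱼ exp(−ΔAICⱼ/2)*.

The synthetic generator produces class-specific seasonal EVI with site,
interannual and observation noise, reliability dropouts, a DEM, country /
municipality / biome polygons, scripted class transitions that create
linear hexagon-level trends, and municipality-level population / nighttime
lights change tied to abandonment — all with recorded ground truth. See
`docs/methods.md` for the model and every default.

## Worked example

Generate a 100 × 100-pixel world with a scripted woody→pasture conversion
(6%/yr of the region's woody pixels from 2002) and run the full pipeline:

```python
from woodytrends.pipeline import PipelineConfig, run_pipeline
from woodytrends.synthetic import LandscapeConfig, TransitionScript
from woodytrends.reporting import make_table1

land = LandscapeConfig(
    nx=100, ny=100, hex_width_km=2.0, seed=1,
    transitions=(TransitionScript((10, 40, 10, 40), "woody", "pasture", 2002, 0.06),),
)
cfg = PipelineConfig(landscape=land, rf_n_estimators=100, n_train_per_class=200)
res = run_pipeline(cfg)
print(res.trend_summary)
print(make_table1(res.zone_table).to_string(index=False))
```

prints

```
{'n_significant': 27, 'loss_pct': 88.9, 'gain_pct': 11.1, 'n_hexagons': 187,
 'n_gain': 3, 'n_loss': 24, 'n_none': 160, 'alpha': 0.05}
Elevation zone (m)  Woody loss (ha)  % loss  Woody gain (ha)  % gain  Net change (ha)
       1,000–1,499             -812    -6.3                0     0.0             -812
       1,500–1,999            -1212    -9.2               31     0.2            -1181
       2,000–2,499                0     0.0                0     0.0                0
       2,500–2,999               -6    -0.0                0     0.0               -6
       3,000–3,499                0     0.0               25     0.2               25
       3,500–3,999                0     0.0                0     0.0                0
            >4,000                0     0.0                0     0.0                0
             Total            -2031     NaN               56     NaN            -1975
```

Of 187 study hexagons, 27 show a significant 14-year trend; 24 are losses
concentrated where the conversion was scripted (the affected low-elevation
zones), and the accounting identity net = loss + gain holds in every row.
The woody/non-woody map accuracy against the synthetic truth here is 97.3%.

A thin CLI mirrors the stages
(`woodytrends synth|features|classify|hexgrid|trends|drivers|report|all
--config cfg.yaml --seed N --out DIR`), writing TIFF rasters, GeoJSON
layers and CSV tables.

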