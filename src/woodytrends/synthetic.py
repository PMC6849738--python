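"""Fully truth-labeled synthetic study region.

Emulates every input of the woody-vegetation-change analysis so the whole
pipeline is testable without satellite downloads: per-pixel 16-day composite
series (EVI + blue/red/NIR/MIR) with class-specific phenology, pixel
reliability codes, a DEM with an elevation gradient, country/municipality/
biome polygon layers, scripted land-cover transitions that create
hexagon-level linear trends, and per-municipality rural-population and
nighttime-lights change tied to abandonment intensity.

The world is planar equal-area (meters); pixels are 250 m so each covers
6.25 ha.  Phenology is a sinusoid (crops get a second harmonic to mimic
cropping cycles) plus three noise scales: a per-pixel site effect, a
per-pixel-year interannual anomaly (droughts/fires make real composite
series fluctuate between years), and per-observation noise.  Reliability
codes are {0 good, 3 unreliable}; only code 3 is ever acted on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point
from shapely.ops import voronoi_diagram

from . import hexgrid
from .features import COMPOSITE_DOY, CompositeSeries
from .trends import ELEV_ZONE_LABELS

CLASS_CODES = {"cropland": 1, "pasture": 2, "woody": 3, "plantation": 4, "other": 5}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}
WOODY_CODE = CLASS_CODES["woody"]
UNRELIABLE = 3


@dataclass(frozen=True)
class ClassPhenology:
    """Seasonal EVI model for one land-cover class.

    EVI(doy) = level + amplitude*(sin(2*pi*doy/365 + phase)
                                  + second_harmonic*sin(4*pi*doy/365 + phase))
    plus noise; the four reflectance bands are flat means plus noise.
    """

    evi_level: float
    evi_amplitude: float
    phase: float = 0.3
    second_harmonic: float = 0.0
    band_means: tuple[float, float, float, float] = (0.04, 0.08, 0.30, 0.18)
    noise_sd_evi: float = 0.04
    noise_sd_band: float = 0.02


#: realistic defaults: woody is high-level/low-amplitude, grass/pasture lower
#: level with a stronger season, crops double-peaked, bare 'other' dark & flat
DEFAULT_PHENOLOGY = {
    "cropland": ClassPhenology(0.35, 0.25, phase=0.0, second_harmonic=0.5,
                               band_means=(0.04, 0.07, 0.30, 0.18)),
    "pasture": ClassPhenology(0.42, 0.18, band_means=(0.04, 0.08, 0.30, 0.20)),
    "woody": ClassPhenology(0.58, 0.08, band_means=(0.03, 0.05, 0.32, 0.12)),
    "plantation": ClassPhenology(0.52, 0.10, band_means=(0.03, 0.05, 0.33, 0.14)),
    "other": ClassPhenology(0.12, 0.03, phase=0.0, band_means=(0.10, 0.15, 0.20, 0.25)),
}


@dataclass(frozen=True)
class TransitionScript:
    """Scripted conversion: inside ``region`` (row0, row1, col0, col1; half-open
    pixel box), ``annual_fraction`` of the pixels that held ``from_class`` at
    ``start_year`` convert to ``to_class`` each year, in a fixed seeded order,
    producing a linear hexagon-level trend."""

    region: tuple[int, int, int, int]
    from_class: str
    to_class: str
    start_year: int
    annual_fraction: float


@dataclass(frozen=True)
class ElevationParams:
    """DEM = base + relief * (northing fraction) + smoothed Gaussian noise."""

    base_m: float = 900.0
    relief_m: float = 2600.0
    noise_sd_m: float = 120.0
    smooth_sigma_px: float = 6.0


@dataclass(frozen=True)
class DriverEffects:
    """Generating logistic model linking hexagon forest-gain probability to
    covariates, and the municipality-level change magnitudes.

    ``elev_zone_effects`` / ``country_effects`` are treatment-coded offsets
    (first level = 0 by construction).  ``dpop_coef`` < 0 encodes gain
    associated with rural-population decline.
    """

    intercept: float = 0.3
    country_effects: tuple[float, ...] = (0.0, 0.5, -0.4)
    elev_zone_effects: tuple[float, ...] = (0.0, 0.8, 1.0, 0.9, 0.6, 0.2, 0.8)
    dpop_coef: float = -0.006
    slope_coef: float = 0.0
    ntl_coef: float = 0.0
    pop_effect: float = 400.0   # persons lost per unit abandonment fraction
    pop_noise_sd: float = 40.0
    ntl_effect: float = -2.0
    ntl_noise_sd: float = 0.5


@dataclass
class LandscapeConfig:
    """Everything needed to generate one synthetic study region."""

    nx: int = 120
    ny: int = 120
    pixel_size_m: float = 250.0
    years: tuple[int, ...] = tuple(range(2001, 2015))
    composites_per_year: int = 23
    phenology: dict = field(default_factory=lambda: dict(DEFAULT_PHENOLOGY))
    pixel_site_sd: float = 0.05       # between-pixel EVI level spread
    pixel_amp_sd: float = 0.05        # between-pixel amplitude spread
    interannual_sd: float = 0.03      # per-pixel-year EVI anomaly
    dropout_prob: float = 0.05
    transitions: tuple[TransitionScript, ...] = ()
    elevation: ElevationParams = field(default_factory=ElevationParams)
    n_countries: int = 3
    n_municipalities: int = 12
    biome_elev_edges: tuple[float, ...] = (1500.0, 3000.0)
    biome_names: tuple[str, ...] = ("dry_forest", "moist_forest", "montane_grassland")
    class_fractions: dict = field(
        default_factory=lambda: {
            "cropland": 0.15, "pasture": 0.30, "woody": 0.40,
            "plantation": 0.05, "other": 0.10,
        }
    )
    patch_sigma_px: float = 4.0
    hex_width_km: float = 11.547
    driver_effects: DriverEffects = field(default_factory=DriverEffects)
    seed: int = 0

    def __post_init__(self):
        if self.composites_per_year < 2:
            raise ValueError("composites per year must be >= 2")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        if list(self.years) != list(range(self.years[0], self.years[-1] + 1)):
            raise ValueError("years must be consecutive")
        for t in self.transitions:
            if not 0.0 <= t.annual_fraction <= 1.0:
                raise ValueError("conversion fraction must be in [0, 1]")
            for cls in (t.from_class, t.to_class):
                if cls not in CLASS_CODES:
                    raise ValueError(f"unknown class {cls!r}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.nx * self.pixel_size_m, self.ny * self.pixel_size_m)


@dataclass
class TruthTables:
    """Ground truth for every downstream stage."""

    pixel_class: np.ndarray                 # (n_years, ny, nx) uint8
    hex_woody_series: pd.DataFrame          # hex_id x years, true woody area (ha)
    hex_trend_direction: pd.Series          # hex_id -> gain/loss/none
    municipality: pd.DataFrame              # name, dpop, dntl, abandonment_frac
    association: dict                       # recorded generating directions


@dataclass
class Landscape:
    """Generated world: rasters, polygon layers, lattice truth, and the
    deterministic composite generator for each year."""

    config: LandscapeConfig
    dem: np.ndarray
    cell_x: np.ndarray
    cell_y: np.ndarray
    truth: np.ndarray                       # (n_years, ny, nx) uint8
    countries: pd.DataFrame
    municipalities: pd.DataFrame
    biomes: pd.DataFrame
    grid: pd.DataFrame
    site_level: np.ndarray                  # (ny, nx)
    site_amp: np.ndarray
    truth_tables: TruthTables | None = None

    @property
    def n_pixels(self) -> int:
        return self.config.nx * self.config.ny

    def pixel_zone(self) -> np.ndarray:
        """Mapping-zone (biome band) name of every pixel, raveled row-major."""
        edges = _biome_y_edges(self.config)
        gy = np.repeat(self.cell_y, self.config.nx)
        zone_idx = np.searchsorted(edges, gy, side="right")
        return np.asarray(self.config.biome_names, dtype=object)[zone_idx]

    def composites_for_year(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        """(values (n_px, 23, 5) float32, reliability (n_px, 23) uint8) for one
        year; deterministic for a fixed config seed."""
        cfg = self.config
        yi = list(cfg.years).index(year)
        rng = np.random.default_rng([cfg.seed, 7, yi])
        n = self.n_pixels
        cls = self.truth[yi].ravel()

        level = np.zeros(6); amp = np.zeros(6); phase = np.zeros(6)
        harm = np.zeros(6); bands = np.zeros((6, 4))
        sd_evi = np.zeros(6); sd_band = np.zeros(6)
        for name, code in CLASS_CODES.items():
            p = cfg.phenology[name]
            level[code], amp[code], phase[code] = p.evi_level, p.evi_amplitude, p.phase
            harm[code] = p.second_harmonic
            bands[code] = p.band_means
            sd_evi[code], sd_band[code] = p.noise_sd_evi, p.noise_sd_band

        doy = COMPOSITE_DOY[: cfg.composites_per_year]
        theta = 2.0 * math.pi * doy / 365.0
        anom = rng.normal(0.0, cfg.interannual_sd, n).astype(np.float32)
        site_l = self.site_level.ravel()
        site_a = self.site_amp.ravel()
        a = np.clip(amp[cls] + site_a, 0.0, None)[:, None]
        seasonal = (
            np.sin(theta[None, :] + phase[cls][:, None])
            + harm[cls][:, None] * np.sin(2 * theta[None, :] + phase[cls][:, None])
        )
        evi = (
            level[cls][:, None] + site_l[:, None] + anom[:, None]
            + a * seasonal
            + rng.normal(0.0, 1.0, (n, doy.size)).astype(np.float32) * sd_evi[cls][:, None]
        )
        np.clip(evi, -0.2, 1.0, out=evi)

        values = np.empty((n, doy.size, 5), dtype=np.float32)
        values[:, :, 0] = evi
        band_noise = rng.normal(0.0, 1.0, (n, doy.size, 4)).astype(np.float32)
        values[:, :, 1:] = (
            bands[cls][:, None, :]
            + 0.2 * site_l[:, None, None]
            + band_noise * sd_band[cls][:, None, None]
        )
        np.clip(values[:, :, 1:], 0.0, 1.0, out=values[:, :, 1:])

        if cfg.dropout_prob > 0:
            rel = (rng.random((n, doy.size)) < cfg.dropout_prob).astype(np.uint8) * UNRELIABLE
        else:
            rel = np.zeros((n, doy.size), dtype=np.uint8)
        return values, rel

    def woody_masks(self, from_truth: bool = True) -> dict[int, np.ndarray]:
        return {
            yr: self.truth[i] == WOODY_CODE
            for i, yr in enumerate(self.config.years)
        }


def generate_composite_series(
    class_label: str,
    year_index: int,
    phenology: dict | None = None,
    seed: int = 0,
    dropout_prob: float = 0.0,
    n_composites: int = 23,
) -> CompositeSeries:
    """One pixel-year composite series for a class (no site effects).

    EVI is clipped to [-0.2, 1.0]; reliability codes are sampled
    independently per observation.  Unknown classes fail.
    """
    phenology = phenology or DEFAULT_PHENOLOGY
    if class_label not in phenology:
        raise KeyError(f"no phenology parameters for class {class_label!r}")
    p = phenology[class_label]
    rng = np.random.default_rng([seed, 11, year_index])
    doy = COMPOSITE_DOY[:n_composites]
    theta = 2.0 * math.pi * doy / 365.0
    seasonal = np.sin(theta + p.phase) + p.second_harmonic * np.sin(2 * theta + p.phase)
    evi = p.evi_level + p.evi_amplitude * seasonal + rng.normal(0.0, p.noise_sd_evi, doy.size)
    evi = np.clip(evi, -0.2, 1.0)
    bands = np.asarray(p.band_means)[None, :] + rng.normal(
        0.0, p.noise_sd_band, (doy.size, 4)
    )
    values = np.column_stack([evi, np.clip(bands, 0.0, 1.0)])
    rel = (rng.random(doy.size) < dropout_prob).astype(np.uint8) * UNRELIABLE
    return CompositeSeries(values, rel, doy)


def _biome_y_edges(cfg: LandscapeConfig) -> np.ndarray:
    """Northing coordinates where the mean elevation profile crosses the biome
    elevation edges (the DEM gradient runs south to north)."""
    e = cfg.elevation
    height = cfg.ny * cfg.pixel_size_m
    fr = (np.asarray(cfg.biome_elev_edges) - e.base_m) / max(e.relief_m, 1e-9)
    return np.clip(fr, 0.0, 1.0) * height


def _voronoi_layer(
    n_cells: int, extent, rng: np.random.Generator, prefix: str
) -> pd.DataFrame:
    xmin, ymin, xmax, ymax = extent
    box = shapely.box(*extent)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_cells), rng.uniform(ymin, ymax, n_cells)]
    )
    cells = voronoi_diagram(MultiPoint(pts), envelope=box)
    polys, names = [], []
    for geom in cells.geoms:
        clipped = geom.intersection(box)
        if clipped.is_empty:
            continue
        # name by the seed point the cell contains, for determinism
        for i, (px, py) in enumerate(pts):
            if geom.covers(Point(px, py)):
                polys.append(clipped)
                names.append(f"{prefix}{i:02d}")
                break
    df = pd.DataFrame({"name": names, "geometry": polys})
    return df.sort_values("name", ignore_index=True)


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate the complete synthetic study region (deterministic per seed)."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    ny, nx = cfg.ny, cfg.nx
    px = cfg.pixel_size_m
    cell_x = (np.arange(nx) + 0.5) * px
    cell_y = (np.arange(ny) + 0.5) * px

    e = cfg.elevation
    dem = (
        e.base_m
        + e.relief_m * (cell_y[:, None] / (ny * px)) * np.ones((1, nx))
        + gaussian_filter(rng.normal(0.0, 1.0, (ny, nx)), e.smooth_sigma_px)
        * e.noise_sd_m
    )

    # spatially coherent initial class patches via quantiles of a smooth field
    g = gaussian_filter(rng.normal(0.0, 1.0, (ny, nx)), cfg.patch_sigma_px)
    order = ["cropland", "pasture", "woody", "plantation", "other"]
    fr = np.array([cfg.class_fractions[c] for c in order], dtype=float)
    fr = fr / fr.sum()
    edges = np.quantile(g, np.cumsum(fr)[:-1])
    idx = np.searchsorted(edges, g, side="right")
    initial = np.array([CLASS_CODES[c] for c in order], dtype=np.uint8)[idx]

    n_years = len(cfg.years)
    truth = np.empty((n_years, ny, nx), dtype=np.uint8)
    truth[0] = initial
    plans = []
    for t in cfg.transitions:
        r0, r1, c0, c1 = t.region
        sub = np.zeros((ny, nx), dtype=bool)
        sub[r0:r1, c0:c1] = True
        elig = np.flatnonzero(sub.ravel() & (initial.ravel() == CLASS_CODES[t.from_class]))
        elig = rng.permutation(elig)
        plans.append((t, elig))
    for yi, yr in enumerate(cfg.years):
        if yi > 0:
            truth[yi] = truth[yi - 1]
        flat = truth[yi].ravel()
        for t, elig in plans:
            if yr < t.start_year:
                continue
            quota = min(
                len(elig), round(t.annual_fraction * len(elig) * (yr - t.start_year + 1))
            )
            flat[elig[:quota]] = CLASS_CODES[t.to_class]
        truth[yi] = flat.reshape(ny, nx)

    countries = _voronoi_layer(cfg.n_countries, cfg.extent, rng, "country_")
    munis = _voronoi_layer(cfg.n_municipalities, cfg.extent, rng, "muni_")
    ye = np.concatenate([[0.0], _biome_y_edges(cfg), [ny * px]])
    biomes = pd.DataFrame(
        {
            "name": list(cfg.biome_names),
            "geometry": [
                shapely.box(0.0, ye[i], nx * px, max(ye[i + 1], ye[i] + 1e-6))
                for i in range(len(cfg.biome_names))
            ],
        }
    )

    grid = hexgrid.make_hexgrid(cfg.extent, cfg.hex_width_km)
    site_level = rng.normal(0.0, cfg.pixel_site_sd, (ny, nx)).astype(np.float32)
    site_amp = rng.normal(0.0, cfg.pixel_amp_sd, (ny, nx)).astype(np.float32)

    land = Landscape(
        config=cfg, dem=dem, cell_x=cell_x, cell_y=cell_y, truth=truth,
        countries=countries, municipalities=munis, biomes=biomes, grid=grid,
        site_level=site_level, site_amp=site_amp,
    )
    land.truth_tables = _build_truth_tables(land)
    return land


def _build_truth_tables(land: Landscape) -> TruthTables:
    cfg = land.config
    series = hexgrid.woody_area_by_hexagon_year(
        land.woody_masks(), land.grid, land.cell_x, land.cell_y
    )
    net = series[cfg.years[-1]] - series[cfg.years[0]]
    direction = pd.Series(
        np.select([net > hexgrid.PIXEL_AREA_HA, net < -hexgrid.PIXEL_AREA_HA],
                  ["gain", "loss"], default="none"),
        index=series.index, name="true_direction",
    )
    muni = generate_driver_surface(land)
    assoc = {
        "dpop_vs_abandonment": "negative",
        "dntl_vs_abandonment": "negative" if cfg.driver_effects.ntl_effect < 0 else "positive",
    }
    return TruthTables(land.truth, series, direction, muni, assoc)


def generate_driver_surface(land: Landscape) -> pd.DataFrame:
    """Per-municipality rural-population and nighttime-lights change.

    Municipalities containing scripted abandonment (conversion into woody
    from pasture/cropland) receive negative population change proportional
    to the abandoned fraction of their area, plus Gaussian noise; same for
    NTL with its own effect size.  Deterministic per config seed.
    """
    cfg = land.config
    de = cfg.driver_effects
    rng = np.random.default_rng([cfg.seed, 3])
    first, last = land.truth[0], land.truth[-1]
    gained = (last == WOODY_CODE) & np.isin(first, [CLASS_CODES["pasture"], CLASS_CODES["cropland"]])
    gx, gy = np.meshgrid(land.cell_x, land.cell_y)
    pts = shapely.points(gx.ravel(), gy.ravel())

    rows = []
    for _, m in land.municipalities.iterrows():
        inside = shapely.contains(m["geometry"], pts)
        n_in = int(inside.sum())
        ab = float(gained.ravel()[inside].sum()) / max(n_in, 1)
        dpop = -de.pop_effect * ab + rng.normal(0.0, de.pop_noise_sd)
        dntl = de.ntl_effect * ab + rng.normal(0.0, de.ntl_noise_sd)
        rows.append(
            {"name": m["name"], "geometry": m["geometry"], "n_pixels": n_in,
             "abandonment_frac": ab, "dpop": dpop, "dntl": dntl}
        )
    return pd.DataFrame(rows)


def sample_training_pixels(
    land: Landscape, year: int, n_per_class: int, seed: int = 0
) -> pd.DataFrame:
    """Truth-labeled training pixels for one reference year (the synthetic
    counterpart of digitizing samples from dated high-resolution imagery)."""
    yi = list(land.config.years).index(year)
    rng = np.random.default_rng([seed, 5])
    flat = land.truth[yi].ravel()
    zones = land.pixel_zone()
    rows = []
    for name, code in CLASS_CODES.items():
        pool = np.flatnonzero(flat == code)
        if pool.size == 0:
            continue
        take = rng.choice(pool, size=min(n_per_class, pool.size), replace=False)
        for pix in take:
            rows.append(
                {"pixel_id": int(pix), "row": int(pix // land.config.nx),
                 "col": int(pix % land.config.nx), "label": name,
                 "year": year, "zone": zones[pix]}
            )
    return pd.DataFrame(rows)


ELEV_ZONE_LEVELS = ELEV_ZONE_LABELS


def simulate_driver_records(
    n: int, effects: DriverEffects | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Record-level generating model for driver parameter recovery.

    Samples ``n`` significant hexagons with country, elevation class, mean
    slope, delta-NTL and delta-rural-population covariates, and draws the
    gain/loss outcome from the logistic generating model in ``effects``.
    Returns (records, truth) where ``truth`` holds the generating
    coefficients and term set.
    """
    de = effects or DriverEffects()
    rng = np.random.default_rng([seed, 13])
    countries = np.array([f"country_{i:02d}" for i in range(len(de.country_effects))])
    ci = rng.integers(0, len(countries), n)
    zi = rng.integers(0, len(de.elev_zone_effects), n)
    slope = rng.gamma(4.0, 3.0, n)
    dntl = rng.normal(0.5, 1.0, n)
    dpop = rng.normal(-20.0, 150.0, n)
    logit = (
        de.intercept
        + np.asarray(de.country_effects)[ci]
        + np.asarray(de.elev_zone_effects)[zi]
        + de.dpop_coef * dpop
        + de.slope_coef * slope
        + de.ntl_coef * dntl
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    outcome = (rng.random(n) < p).astype(int)
    records = pd.DataFrame(
        {
            "hex_id": [f"h{i:05d}" for i in range(n)],
            "outcome": outcome,
            "country": countries[ci],
            "elev_zone": np.asarray(ELEV_ZONE_LEVELS, dtype=object)[zi],
            "slope": slope,
            "dntl": dntl,
            "dpop": dpop,
        }
    )
    truth = {
        "terms": ("elev_zone", "country", "dpop"),
        "dpop_coef": de.dpop_coef,
        "intercept": de.intercept,
        "country_effects": de.country_effects,
        "elev_zone_effects": de.elev_zone_effects,
    }
    return records, truth
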