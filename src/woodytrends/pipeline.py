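"""End-to-end orchestration: synthetic world -> features -> classification ->
hexagon grid -> trends -> drivers, with all tables and a run manifest.

One master seed drives every stage; stage seeds are derived from it so a
rerun with the same configuration reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classification, drivers, hexgrid, io, reporting, trends
from .synthetic import (
    DriverEffects,
    ElevationParams,
    Landscape,
    LandscapeConfig,
    TransitionScript,
    generate_landscape,
    sample_training_pixels,
)
from .features import build_feature_table

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's options; defaults reproduce the reference analysis
    choices (alpha 0.05, no multiplicity correction, plantation not woody,
    one 12-month + two half + three third windows)."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    alpha: float = trends.DEFAULT_ALPHA
    bh_correction: bool = False
    include_plantation: bool = False
    reference_year: int = 2005
    n_train_per_class: int = 300
    rf_n_estimators: int = 500
    net_from_fit: bool = False

    @property
    def seed(self) -> int:
        return self.landscape.seed

    def stage_seed(self, stage: int) -> int:
        return int((self.seed * 1_000_003 + stage) % (2**31 - 1))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    land_raw = raw.pop("landscape", {})
    if "transitions" in land_raw:
        land_raw["transitions"] = tuple(
            TransitionScript(**{**t, "region": tuple(t["region"])})
            for t in land_raw["transitions"]
        )
    if "elevation" in land_raw:
        land_raw["elevation"] = ElevationParams(**land_raw["elevation"])
    if "driver_effects" in land_raw:
        land_raw["driver_effects"] = DriverEffects(**land_raw["driver_effects"])
    if "years" in land_raw:
        land_raw["years"] = tuple(land_raw["years"])
    return PipelineConfig(landscape=LandscapeConfig(**land_raw), **raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    landscape: Landscape
    maps: dict
    study: pd.DataFrame
    excluded: pd.DataFrame
    series: pd.DataFrame
    results: pd.DataFrame
    trend_summary: dict
    zone_table: pd.DataFrame
    country_table: pd.DataFrame
    accuracy: classification.ConfusionMatrix | None
    accuracy_woody: classification.ConfusionMatrix | None
    driver_records: pd.DataFrame | None
    akaike: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    assess_year: int = 2013,
    n_assess: int = 2000,
) -> PipelineResult:
    """Execute every stage; optionally write all outputs under ``out_dir``.

    Accuracy is assessed by comparing the ``assess_year`` map against the
    synthetic truth at ``n_assess`` random reference pixels (the synthetic
    counterpart of spot-checking against high-resolution imagery).
    """
    cfg_l = cfg.landscape
    log.info("stage synthetic_landscape: %dx%d pixels", cfg_l.nx, cfg_l.ny)
    land = generate_landscape(cfg_l)
    pixel_zone = land.pixel_zone()
    shape = (cfg_l.ny, cfg_l.nx)

    # features are built per year and classified immediately so only one
    # year's table is resident at a time (the stacks get large)
    log.info("stage features + classification: %d years", len(cfg_l.years))
    ref_table = build_feature_table(*land.composites_for_year(cfg.reference_year))
    samples = sample_training_pixels(
        land, cfg.reference_year, cfg.n_train_per_class, seed=cfg.stage_seed(2)
    )
    training = classification.pair_samples(samples, {cfg.reference_year: ref_table})
    models = {
        zone: classification.train_zone_model(
            training, zone, n_estimators=cfg.rf_n_estimators, seed=cfg.stage_seed(3)
        )
        for zone in sorted(np.unique(pixel_zone))
    }
    maps = {}
    for yr in cfg_l.years:
        table = (
            ref_table
            if yr == cfg.reference_year
            else build_feature_table(*land.composites_for_year(yr))
        )
        maps[yr] = classification.classify_annual(table, pixel_zone, models, shape)
    del ref_table, table

    acc = acc_woody = None
    if assess_year in maps:
        rng = np.random.default_rng([cfg.stage_seed(4)])
        yi = list(cfg_l.years).index(assess_year)
        idx = rng.choice(cfg_l.nx * cfg_l.ny, size=min(n_assess, cfg_l.nx * cfg_l.ny),
                         replace=False)
        acc, acc_woody = classification.assess_accuracy(
            maps[assess_year].ravel()[idx], land.truth[yi].ravel()[idx]
        )
        log.info("woody/non-woody accuracy %.1f%%", 100 * acc_woody.overall)

    log.info("stage hexgrid")
    enriched = hexgrid.attach_attributes(
        land.grid, land.dem, land.cell_x, land.cell_y, land.countries, land.biomes
    )
    study, excluded = hexgrid.filter_study_hexagons(enriched)
    woody_masks = {
        yr: classification.binarize_woody(m, cfg.include_plantation)
        for yr, m in maps.items()
    }
    series = hexgrid.woody_area_by_hexagon_year(
        woody_masks, study, land.cell_x, land.cell_y
    )

    log.info("stage trend_analysis: %d study hexagons", len(study))
    results, trend_summary = trends.classify_hexagons(
        series, alpha=cfg.alpha, bh_correction=cfg.bh_correction
    )
    zone_table = trends.summarize_by_zone(results, study)
    country_table = trends.summarize_by_country(results, study)

    log.info("stage drivers")
    slope_raster = drivers.dem_slope(land.dem, cfg_l.pixel_size_m)
    slope_hex = drivers.mean_slope_by_hexagon(
        slope_raster, study, land.cell_x, land.cell_y
    ).set_axis(study["hex_id"])
    muni = land.truth_tables.municipality
    dpop_hex = drivers.rescale_to_hexagons(muni.set_index("name")["dpop"], muni, study)
    dntl_hex = drivers.rescale_to_hexagons(muni.set_index("name")["dntl"], muni, study)
    records = drivers.build_driver_records(
        results, study, slope_hex, dntl_hex, dpop_hex
    )
    akaike = None
    if len(records) >= 30 and records["outcome"].nunique() == 2:
        usable_terms = tuple(
            t for t in drivers.TERMS
            if (records[t].nunique() > 1 if t in drivers.CATEGORICAL else True)
        )
        _, akaike = drivers.fit_all_models(records, usable_terms)
    else:
        log.warning(
            "driver model selection skipped: %d significant hexagons, "
            "%d outcome class(es)", len(records), records["outcome"].nunique()
            if len(records) else 0,
        )

    manifest = {
        "package_version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in range(5)},
        "config": dataclasses.asdict(cfg),
        "n_study_hexagons": len(study),
        "trend_summary": trend_summary,
    }
    result = PipelineResult(
        cfg, land, maps, study, excluded, series, results, trend_summary,
        zone_table, country_table, acc, acc_woody, records, akaike, manifest,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(res: PipelineResult, out: Path):
    """Write every table, layer and raster plus the run manifest."""
    out.mkdir(parents=True, exist_ok=True)
    cfg_l = res.config.landscape
    io.write_raster(out / "dem.tif", res.landscape.dem.astype(np.float32),
                    cfg_l.pixel_size_m)
    for yr, m in res.maps.items():
        io.write_raster(out / f"landcover_{yr}.tif", m, cfg_l.pixel_size_m)
    io.write_geojson(out / "countries.geojson", res.landscape.countries)
    io.write_geojson(out / "municipalities.geojson",
                     res.landscape.truth_tables.municipality)
    io.write_geojson(out / "biomes.geojson", res.landscape.biomes)
    hex_layer = res.study.merge(
        res.results.reset_index().rename(columns={"index": "hex_id"}),
        on="hex_id", how="left",
    )
    io.write_geojson(out / "hexagons.geojson", hex_layer)
    res.series.to_csv(out / "woody_area_series.csv")
    res.results.to_csv(out / "trend_results.csv")
    reporting.make_table1(res.zone_table).to_csv(out / "table_zone_summary.csv",
                                                 index=False)
    res.country_table.to_csv(out / "table_country_summary.csv", index=False)
    reporting.make_figure2_data(res.country_table).to_csv(
        out / "figure2_data.csv", index=False
    )
    if res.driver_records is not None:
        res.driver_records.to_csv(out / "driver_records.csv", index=False)
    if res.akaike is not None:
        res.akaike.drop(columns=["terms"]).to_csv(out / "model_selection.csv",
                                                  index=False)
        reporting.make_table3(res.akaike).to_csv(out / "table_best_models.csv",
                                                 index=False)
    if res.accuracy is not None:
        res.accuracy.as_frame().to_csv(out / "confusion_5class.csv")
        res.accuracy_woody.as_frame().to_csv(out / "confusion_woody.csv")
    io.write_manifest(out / "manifest.json", res.manifest)
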