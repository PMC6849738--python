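"""Covariates and exhaustive logistic model selection for gain-vs-loss drivers.

For every hexagon with a significant trend the binary outcome (gain = 1,
loss = 0) is related to five candidate predictors -- country, elevation
class, mean slope, change in nighttime lights (2001-2011) and change in
rural population (2001-2011) -- by fitting all 2^5 = 32 main-effect logistic
regressions and ranking them by AIC with Akaike weights
w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2) over the full model set.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import hexgrid

log = logging.getLogger(__name__)

#: candidate predictors in their canonical order; categoricals dummy-coded
#: against the alphabetically-first reference level
TERMS = ("elev_zone", "country", "slope", "dntl", "dpop")
CATEGORICAL = {"elev_zone", "country"}


def dem_slope(dem: np.ndarray, cell_size_m: float) -> np.ndarray:
    """Terrain slope in degrees by Horn's 3x3 finite-difference method.

    Edge cells use edge replication.  Fails on a single-row/column DEM.
    """
    z = np.asarray(dem, dtype=float)
    if z.ndim != 2 or min(z.shape) < 2:
        raise ValueError(f"DEM must be 2-D with both dimensions >= 2, got {z.shape}")
    p = np.pad(z, 1, mode="edge")
    a, b, c = p[:-2, :-2], p[:-2, 1:-1], p[:-2, 2:]
    d, f = p[1:-1, :-2], p[1:-1, 2:]
    g, h, i = p[2:, :-2], p[2:, 1:-1], p[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size_m)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cell_size_m)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def mean_slope_by_hexagon(
    slope: np.ndarray,
    grid: pd.DataFrame,
    cell_x: np.ndarray,
    cell_y: np.ndarray,
) -> pd.Series:
    """Mean slope over raster cells whose centers fall inside each hexagon;
    hexagons with no cells get NaN (missing)."""
    gx, gy = np.meshgrid(cell_x, cell_y)
    assigned = hexgrid.assign_points(grid, gx.ravel(), gy.ravel())
    s = pd.Series(slope.ravel(), index=assigned)
    out = s.groupby(level=0).mean()
    return out.reindex(grid["hex_id"]).rename("slope")


def rescale_to_hexagons(
    values: pd.Series,
    polygons: pd.DataFrame,
    grid: pd.DataFrame,
) -> pd.Series:
    """Area-weighted allocation of municipality-level values to hexagons.

    hexagon value = sum over municipalities of value * overlap/municipality
    area, which conserves the regional total when municipalities tessellate
    the hexagons' union.  Hexagons overlapping no municipality get NaN.
    """
    import shapely

    geoms = np.array(grid["geometry"].tolist(), dtype=object)
    total = np.zeros(len(grid))
    any_overlap = np.zeros(len(grid), dtype=bool)
    for name, val in values.items():
        poly = polygons.loc[polygons["name"] == name, "geometry"].iloc[0]
        inter = shapely.area(shapely.intersection(geoms, poly))
        frac = inter / poly.area
        total += val * frac
        any_overlap |= inter > 0
    return pd.Series(np.where(any_overlap, total, np.nan), index=grid["hex_id"].to_numpy())


def enumerate_models(terms: tuple[str, ...] = TERMS) -> list[tuple[str, ...]]:
    """All main-effect subsets of the predictors, intercept-only included,
    in a deterministic order (by size, then term order)."""
    subsets = []
    for k in range(len(terms) + 1):
        subsets.extend(itertools.combinations(terms, k))
    return subsets


@dataclass
class LogisticFit:
    terms: tuple[str, ...]
    aic: float
    k: int                      # number of estimated coefficients
    coefficients: pd.Series
    bse: pd.Series
    converged: bool
    separated: bool

    @property
    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "intercept-only"


def _formula(terms: tuple[str, ...]) -> str:
    rhs = [f"C({t})" if t in CATEGORICAL else t for t in terms]
    return "outcome ~ " + (" + ".join(rhs) if rhs else "1")


def fit_logistic(records: pd.DataFrame, terms: tuple[str, ...]) -> LogisticFit:
    """Maximum-likelihood logistic fit of gain/loss on a term subset.

    AIC = -2 logL + 2k with k the number of estimated coefficients.
    Perfect separation (or non-convergence) is flagged; flagged fits are
    excluded from ranking by :func:`akaike_table`.
    """
    if records["outcome"].nunique() < 2:
        raise ValueError("outcome must contain both gain (1) and loss (0)")
    separated = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.logit(_formula(terms), data=records)
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or np.abs(res.params).max() > 50:
                separated = True
        except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
            log.warning("perfect separation for model %s; excluded from ranking", terms)
            return LogisticFit(terms, float("inf"), 0, pd.Series(dtype=float),
                               pd.Series(dtype=float), False, True)
    if separated:
        log.warning("suspected separation/non-convergence for model %s", terms)
    return LogisticFit(
        terms=terms,
        aic=float(res.aic),
        k=int(res.df_model + 1),
        coefficients=res.params,
        bse=res.bse,
        converged=converged,
        separated=separated,
    )


def akaike_table(fits: list[LogisticFit]) -> pd.DataFrame:
    """Rank fits by AIC with dAIC and Akaike weights over all ranked models."""
    ok = [f for f in fits if not f.separated and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no successful fits to rank")
    df = pd.DataFrame(
        {
            "model": [f.label for f in ok],
            "terms": [f.terms for f in ok],
            "aic": [f.aic for f in ok],
            "k": [f.k for f in ok],
        }
    ).sort_values("aic", kind="stable", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    rel = np.exp(-0.5 * df["delta_aic"].to_numpy())
    df["weight"] = rel / rel.sum()
    return df


def fit_all_models(
    records: pd.DataFrame, terms: tuple[str, ...] = TERMS
) -> tuple[list[LogisticFit], pd.DataFrame]:
    """Fit every subset model and return (fits, ranked Akaike table)."""
    usable = records.dropna(subset=[t for t in terms])
    if len(usable) < len(records):
        log.info("dropped %d records with missing covariates", len(records) - len(usable))
    fits = [fit_logistic(usable, t) for t in enumerate_models(terms)]
    return fits, akaike_table(fits)


def build_driver_records(
    results: pd.DataFrame,
    attributes: pd.DataFrame,
    slope_by_hex: pd.Series,
    dntl_by_hex: pd.Series,
    dpop_by_hex: pd.Series,
) -> pd.DataFrame:
    """Assemble one DriverRecord per significant hexagon (gain=1, loss=0)."""
    from .trends import elevation_zone

    sig = results[results["direction"].isin(["gain", "loss"])]
    attrs = attributes.set_index("hex_id") if "hex_id" in attributes.columns else attributes
    rec = pd.DataFrame(index=sig.index)
    rec["outcome"] = (sig["direction"] == "gain").astype(int)
    rec["country"] = attrs["country"].reindex(sig.index)
    rec["elev_zone"] = attrs["median_elev_m"].reindex(sig.index).map(elevation_zone)
    rec["slope"] = slope_by_hex.reindex(sig.index)
    rec["dntl"] = dntl_by_hex.reindex(sig.index)
    rec["dpop"] = dpop_by_hex.reindex(sig.index)
    rec.index.name = "hex_id"
    return rec.reset_index()


def recover_drivers(
    records: pd.DataFrame, truth: dict, terms: tuple[str, ...] = TERMS
) -> dict:
    """Check whether the generating driver model is recovered.

    Fits the exhaustive model set, then reports (a) the sign and 3-SE
    interval check of the fitted delta-rural-population coefficient against
    the generating one, and (b) the dAIC of the generating term set.
    """
    fits, table = fit_all_models(records, terms)
    gen_terms = tuple(t for t in terms if t in truth["terms"])
    gen_fit = next(f for f in fits if f.terms == gen_terms)
    coef = float(gen_fit.coefficients.get("dpop", np.nan))
    se = float(gen_fit.bse.get("dpop", np.nan))
    truth_coef = truth["dpop_coef"]
    row = table[table["terms"].apply(lambda t: t == gen_terms)]
    delta = float(row["delta_aic"].iloc[0]) if len(row) else float("inf")
    return {
        "dpop_coef_fitted": coef,
        "dpop_coef_truth": truth_coef,
        "dpop_se": se,
        "dpop_sign_recovered": bool(np.sign(coef) == np.sign(truth_coef)),
        "dpop_within_3se": bool(abs(coef - truth_coef) <= 3 * se),
        "generating_terms": gen_terms,
        "generating_delta_aic": delta,
        "best_model": table["model"].iloc[0],
        "table": table,
    }
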