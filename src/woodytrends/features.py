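"""Per-pixel temporal statistics of MODIS-like composite series.

For each of the five variables (EVI, blue, red, NIR, MIR) the classifier
predictors are the mean, standard deviation, minimum, maximum and range of
the reliable observations in six windows of the year: the full 12 months,
two 6-month halves, and three 4-month thirds -- 5 x 6 x 5 = 150 features.
Observations whose pixel-reliability code equals 3 are removed before any
statistic is computed.

Composites are the standard 16-day product: 23 per year, starting on days
of year 1, 17, 33, ..., 353 (the last composite is short).  A composite
belongs to a window according to its start day of year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIABLES = ("evi", "blue", "red", "nir", "mir")
STATISTICS = ("mean", "sd", "min", "max", "range")
UNRELIABLE = 3

#: start day-of-year of each of the 23 composites
COMPOSITE_DOY = 1 + 16 * np.arange(23)

# window boundaries (start-doy intervals, inclusive); halves split at day 182,
# thirds at days 121 and 243
_WINDOW_BOUNDS = {
    "annual": (1, 365),
    "h1": (1, 182),
    "h2": (183, 365),
    "t1": (1, 121),
    "t2": (122, 243),
    "t3": (244, 365),
}
WINDOWS = tuple(_WINDOW_BOUNDS)

#: boolean membership of each composite in each window, shape (n_windows, 23)
WINDOW_MASKS = np.array(
    [(COMPOSITE_DOY >= lo) & (COMPOSITE_DOY <= hi) for lo, hi in _WINDOW_BOUNDS.values()]
)

FEATURE_NAMES = tuple(
    f"{v}_{w}_{s}" for v in VARIABLES for w in WINDOWS for s in STATISTICS
)
N_FEATURES = len(FEATURE_NAMES)  # 150


def monthly_window_masks() -> tuple[tuple[str, ...], np.ndarray]:
    """Alternative reading of the window set: 12 calendar-month windows plus
    the halves and thirds (17 windows).  Not the default; selectable via
    ``build_feature_vector(..., windows="monthly")``."""
    month_start = np.array([1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335, 366])
    names = [f"m{m:02d}" for m in range(1, 13)] + ["h1", "h2", "t1", "t2", "t3"]
    masks = [
        (COMPOSITE_DOY >= month_start[m]) & (COMPOSITE_DOY < month_start[m + 1])
        for m in range(12)
    ]
    masks += [WINDOW_MASKS[i] for i, w in enumerate(WINDOWS) if w != "annual"]
    return tuple(names), np.array(masks)


@dataclass
class CompositeSeries:
    """One pixel-year of composite observations.

    values: (n_obs, 5) array ordered as VARIABLES; reliability: (n_obs,)
    integer codes; doy: (n_obs,) composite start day-of-year.
    """

    values: np.ndarray
    reliability: np.ndarray
    doy: np.ndarray = field(default_factory=lambda: COMPOSITE_DOY.copy())

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.reliability = np.asarray(self.reliability)
        self.doy = np.asarray(self.doy)
        if len(self.reliability) != len(self.values):
            raise ValueError("reliability codes must parallel observations")


def mask_unreliable(series: CompositeSeries) -> CompositeSeries:
    """Drop observations flagged unreliable (code 3), preserving order."""
    keep = series.reliability != UNRELIABLE
    return CompositeSeries(
        series.values[keep], series.reliability[keep], series.doy[keep]
    )


def window_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, sample SD, min, max and range of a 1-D observation vector.

    An empty window yields all-NaN (missing, not zero); a single observation
    yields SD NaN (sample SD undefined at n=1).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return dict.fromkeys(STATISTICS, np.nan)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
    return {
        "mean": float(v.mean()),
        "sd": sd,
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
    }


def build_feature_vector(
    series: CompositeSeries, windows: str = "standard", impute: bool = True
) -> np.ndarray:
    """150-entry feature vector (or 425 for the monthly reading) for one series.

    Unreliable observations are removed first.  Windows left empty by the
    reliability screen are imputed with the same statistic from the 12-month
    window when ``impute`` is set; a fully empty year stays NaN.
    """
    if windows == "standard":
        masks, _names = WINDOW_MASKS, WINDOWS
    elif windows == "monthly":
        _names, masks = monthly_window_masks()
        masks = np.vstack([WINDOW_MASKS[0:1], masks])  # annual window kept first
    else:
        raise ValueError(f"unknown window set {windows!r}")

    clean = mask_unreliable(series)
    out = []
    for vi in range(len(VARIABLES)):
        annual = None
        for wi in range(len(masks)):
            in_w = np.isin(clean.doy, COMPOSITE_DOY[masks[wi]])
            stats = window_stats(clean.values[in_w, vi])
            if wi == 0:
                annual = stats
            if impute:
                stats = {
                    k: (annual[k] if np.isnan(stats[k]) else stats[k])
                    for k in STATISTICS
                }
            out.extend(stats[s] for s in STATISTICS)
    return np.array(out)


def build_feature_table(
    values: np.ndarray,
    reliability: np.ndarray,
    pixel_ids: np.ndarray | None = None,
    impute: bool = True,
) -> pd.DataFrame:
    """Vectorized feature extraction for a composite stack.

    values: (n_pixels, 23, 5); reliability: (n_pixels, 23).  Returns a
    DataFrame (n_pixels x 150) with FEATURE_NAMES columns plus ``usable``
    (at least one reliable observation in the year).  Matches
    :func:`build_feature_vector` row-wise.
    """
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 3 or values.shape[1:] != (23, len(VARIABLES)):
        raise ValueError(f"expected (n, 23, 5) stack, got {values.shape}")
    v = values.copy()
    v[np.asarray(reliability) == UNRELIABLE] = np.nan

    n = v.shape[0]
    cols = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-window nan stats
        per_window = {}
        for wi, wname in enumerate(WINDOWS):
            vw = v[:, WINDOW_MASKS[wi], :]
            cnt = np.sum(~np.isnan(vw[:, :, 0]), axis=1)
            stats = {
                "mean": np.nanmean(vw, axis=1),
                "min": np.nanmin(vw, axis=1),
                "max": np.nanmax(vw, axis=1),
            }
            sd = np.nanstd(vw, axis=1, ddof=1)
            sd[cnt <= 1] = np.nan
            stats["sd"] = sd
            stats["range"] = stats["max"] - stats["min"]
            per_window[wname] = stats
    if impute:
        for wname in WINDOWS[1:]:
            for s in STATISTICS:
                miss = np.isnan(per_window[wname][s])
                per_window[wname][s] = np.where(
                    miss, per_window["annual"][s], per_window[wname][s]
                )
    for vi, var in enumerate(VARIABLES):
        for wname in WINDOWS:
            for s in STATISTICS:
                cols[f"{var}_{wname}_{s}"] = per_window[wname][s][:, vi]

    df = pd.DataFrame(cols, index=pixel_ids if pixel_ids is not None else np.arange(n))
    df["usable"] = np.sum(~np.isnan(v[:, :, 0]), axis=1) > 0
    df.index.name = "pixel_id"
    return df
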