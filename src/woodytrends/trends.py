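"""Per-hexagon 14-year linear trend detection and elevation-zone accounting.

Each hexagon's annual woody area (ha) is regressed on calendar year by
ordinary least squares; the two-sided t test on the slope (df = n - 2 = 12)
classifies the hexagon as significant gain (p < alpha, slope > 0),
significant loss (p < alpha, slope < 0) or no trend.  For significant
hexagons the reported net change is the observed endpoint difference,
area(2014) - area(2001).  Gains and losses are then summed within seven
500 m elevation zones from 1,000 m upward and within countries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ELEV_ZONE_LABELS = (
    "1,000–1,499", "1,500–1,999", "2,000–2,499", "2,500–2,999",
    "3,000–3,499", "3,500–3,999", ">4,000",
)
_ZONE_EDGES = np.array([1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0, 4000.0])

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    hex_id: str
    slope: float          # ha / yr
    p_value: float
    direction: str        # gain / loss / none
    net_change: float     # ha, area(last) - area(first); NaN when direction none


def fit_trend(
    series: pd.Series | np.ndarray,
    years: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    hex_id: str = "",
    net_from_fit: bool = False,
) -> TrendResult:
    """OLS of woody area on calendar year for one hexagon.

    Requires the full 14-value series.  A zero-variance series has no
    defined trend and returns direction 'none'.  ``net_from_fit`` reports
    the fitted-endpoint difference instead of the observed one.
    """
    if isinstance(series, pd.Series):
        if years is None:
            years = series.index.to_numpy(dtype=float)
        series = series.to_numpy(dtype=float)
    y = np.asarray(series, dtype=float)
    t = np.asarray(years, dtype=float)
    if y.size != t.size or y.size < 3:
        raise ValueError(f"need a full series (got {y.size} values, {t.size} years)")
    if np.isnan(y).any():
        raise ValueError("series contains missing values")

    if np.ptp(y) == 0.0:
        return TrendResult(hex_id, 0.0, float("nan"), "none", float("nan"))
    fit = stats.linregress(t, y)
    p = float(fit.pvalue)
    slope = float(fit.slope)
    if p < alpha and slope > 0:
        direction = "gain"
    elif p < alpha and slope < 0:
        direction = "loss"
    else:
        direction = "none"
    if direction == "none":
        net = float("nan")
    elif net_from_fit:
        net = slope * (t[-1] - t[0])
    else:
        net = float(y[-1] - y[0])
    return TrendResult(hex_id, slope, p, direction, net)


def fit_all_trends(
    series_table: pd.DataFrame, alpha: float = DEFAULT_ALPHA, net_from_fit: bool = False
) -> pd.DataFrame:
    """Vectorized OLS over a hex_id x year area table.

    Returns a DataFrame indexed by hex_id with slope, p_value, direction and
    net_change columns; equivalent to :func:`fit_trend` row-by-row.
    """
    t = series_table.columns.to_numpy(dtype=float)
    Y = series_table.to_numpy(dtype=float)
    n = t.size
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    slope = (Y @ tc) / sxx
    resid = Y - Y.mean(axis=1, keepdims=True) - slope[:, None] * tc[None, :]
    sse = np.sum(resid**2, axis=1)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    flat = np.ptp(Y, axis=1) == 0.0
    direction = np.select(
        [~flat & (p < alpha) & (slope > 0), ~flat & (p < alpha) & (slope < 0)],
        ["gain", "loss"],
        default="none",
    )
    if net_from_fit:
        net = slope * (t[-1] - t[0])
    else:
        net = Y[:, -1] - Y[:, 0]
    net = np.where(direction == "none", np.nan, net)
    out = pd.DataFrame(
        {
            "slope": np.where(flat, 0.0, slope),
            "p_value": np.where(flat, np.nan, p),
            "direction": direction,
            "net_change": net,
        },
        index=series_table.index,
    )
    return out


def direction_shares(n_loss: int, n_gain: int) -> dict:
    """Loss/gain percentage shares of the significant set, to one decimal.

    With an empty significant set the shares are undefined (NaN)."""
    total = n_loss + n_gain
    if total == 0:
        return {"n_significant": 0, "loss_pct": float("nan"), "gain_pct": float("nan")}
    return {
        "n_significant": total,
        "loss_pct": round(100.0 * n_loss / total, 1),
        "gain_pct": round(100.0 * n_gain / total, 1),
    }


def classify_hexagons(
    series_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Partition hexagons into gain/loss/none and report counts and shares.

    ``bh_correction`` applies Benjamini–Hochberg FDR control across the
    hexagon tests before thresholding (sensitivity option, off by default:
    the reference analysis tests each hexagon at raw alpha)."""
    results = fit_all_trends(series_table, alpha=alpha)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        p = results["p_value"].to_numpy()
        ok = ~np.isnan(p)
        padj = np.full_like(p, np.nan)
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        results["p_adjusted"] = padj
        sig = padj < alpha
        results["direction"] = np.select(
            [sig & (results["slope"] > 0), sig & (results["slope"] < 0)],
            ["gain", "loss"], default="none",
        )
        raw_net = (
            series_table.iloc[:, -1] - series_table.iloc[:, 0]
        ).to_numpy(dtype=float)
        results["net_change"] = np.where(
            results["direction"] == "none", np.nan, raw_net
        )
    n_gain = int((results["direction"] == "gain").sum())
    n_loss = int((results["direction"] == "loss").sum())
    summary = direction_shares(n_loss, n_gain)
    summary.update(
        n_hexagons=len(results),
        n_gain=n_gain,
        n_loss=n_loss,
        n_none=int((results["direction"] == "none").sum()),
        alpha=alpha,
    )
    return results, summary


def elevation_zone(median_elev_m: float) -> str:
    """Zone label for a hexagon's median elevation; half-open 500 m bins,
    the last open-ended above 4,000 m.  Elevations below 1,000 m should have
    been filtered out and raise."""
    if median_elev_m < 1000.0:
        raise ValueError(f"elevation {median_elev_m} m below the 1,000 m study floor")
    i = int(np.searchsorted(_ZONE_EDGES, median_elev_m, side="right")) - 1
    return ELEV_ZONE_LABELS[i]


def summarize_by_zone(
    results: pd.DataFrame, attributes: pd.DataFrame
) -> pd.DataFrame:
    """Per-elevation-zone signed loss, gain, percent of zone area, and net.

    ``results`` is the fit_all_trends output; ``attributes`` carries
    median_elev_m and area_km2 per hex_id (all study hexagons -- the percent
    denominator is the total area of the zone's study hexagons, in ha).
    Returns seven zone rows plus a 'Total' row of column sums.
    """
    attrs = attributes.set_index("hex_id") if "hex_id" in attributes.columns else attributes
    zones = attrs["median_elev_m"].map(elevation_zone)
    joined = results.join(zones.rename("zone"), how="left")
    zone_area_ha = attrs["area_km2"].groupby(zones).sum() * 100.0

    rows = []
    for label in ELEV_ZONE_LABELS:
        sub = joined[joined["zone"] == label]
        loss = float(sub.loc[sub["direction"] == "loss", "net_change"].sum())
        gain = float(sub.loc[sub["direction"] == "gain", "net_change"].sum())
        area = float(zone_area_ha.get(label, 0.0))
        rows.append(
            {
                "zone": label,
                "loss_ha": loss,
                "loss_pct": 100.0 * loss / area if area else 0.0,
                "gain_ha": gain,
                "gain_pct": 100.0 * gain / area if area else 0.0,
                "net_ha": loss + gain,
            }
        )
    table = pd.DataFrame(rows)
    totals = {
        "zone": "Total",
        "loss_ha": table["loss_ha"].sum(),
        "loss_pct": float("nan"),
        "gain_ha": table["gain_ha"].sum(),
        "gain_pct": float("nan"),
        "net_ha": table["net_ha"].sum(),
    }
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)


def zone_table_from_components(
    loss_ha: dict[str, float],
    gain_ha: dict[str, float],
    zone_area_ha: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rebuild the zone accounting table from per-zone loss/gain components.

    Net is loss + gain per zone; the totals row carries column sums.  Used to
    recompute the summary arithmetic when the per-zone components are given
    directly rather than derived from trend results.
    """
    rows = []
    for label in ELEV_ZONE_LABELS:
        loss = float(loss_ha.get(label, 0.0))
        gain = float(gain_ha.get(label, 0.0))
        area = float(zone_area_ha[label]) if zone_area_ha else float("nan")
        rows.append(
            {
                "zone": label,
                "loss_ha": loss,
                "loss_pct": 100.0 * loss / area if zone_area_ha else float("nan"),
                "gain_ha": gain,
                "gain_pct": 100.0 * gain / area if zone_area_ha else float("nan"),
                "net_ha": loss + gain,
            }
        )
    table = pd.DataFrame(rows)
    totals = {
        "zone": "Total",
        "loss_ha": table["loss_ha"].sum(),
        "loss_pct": float("nan"),
        "gain_ha": table["gain_ha"].sum(),
        "gain_pct": float("nan"),
        "net_ha": table["net_ha"].sum(),
    }
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)


def summarize_by_country(
    results: pd.DataFrame, attributes: pd.DataFrame
) -> pd.DataFrame:
    """Per-country per-zone gain/loss plus each country's net over all zones."""
    attrs = attributes.set_index("hex_id") if "hex_id" in attributes.columns else attributes
    zones = attrs["median_elev_m"].map(elevation_zone)
    joined = results.join(zones.rename("zone")).join(attrs["country"])
    rows = []
    for country, csub in joined.groupby("country"):
        for label in ELEV_ZONE_LABELS:
            sub = csub[csub["zone"] == label]
            loss = float(sub.loc[sub["direction"] == "loss", "net_change"].sum())
            gain = float(sub.loc[sub["direction"] == "gain", "net_change"].sum())
            rows.append(
                {"country": country, "zone": label, "loss_ha": loss,
                 "gain_ha": gain, "net_ha": loss + gain}
            )
    table = pd.DataFrame(rows)
    nets = (
        table.groupby("country", as_index=False)["net_ha"].sum()
        .rename(columns={"net_ha": "country_net_ha"})
    )
    return table.merge(nets, on="country")
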