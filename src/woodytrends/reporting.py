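"""Publication-format tables and expert-validation agreement arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd

VERDICTS = ("agree", "disagree", "insufficient")


def agreement_stats(evaluations: pd.DataFrame) -> dict:
    """Counts and percentages of expert agreement with mapped change clusters.

    ``evaluations`` needs a ``verdict`` column from {agree, disagree,
    insufficient}; percentages are over the evaluable clusters
    (agree + disagree), rounded to whole percent as printed.
    """
    if len(evaluations) == 0:
        raise ValueError("no cluster evaluations provided")
    bad = set(evaluations["verdict"].unique()) - set(VERDICTS)
    if bad:
        raise ValueError(f"unknown verdict(s) {bad}")
    counts = evaluations["verdict"].value_counts()
    n_agree = int(counts.get("agree", 0))
    n_disagree = int(counts.get("disagree", 0))
    total = n_agree + n_disagree
    if total == 0:
        raise ValueError("no evaluable clusters (all verdicts insufficient)")
    return {
        "n_agree": n_agree,
        "n_disagree": n_disagree,
        "n_insufficient": int(counts.get("insufficient", 0)),
        "n_evaluable": total,
        "agree_pct": round(100.0 * n_agree / total),
        "disagree_pct": round(100.0 * n_disagree / total),
    }


def make_table1(zone_summary: pd.DataFrame) -> pd.DataFrame:
    """Elevation-zone loss/gain table: areas to whole ha, percents to one
    decimal; 'Total' row carries the column sums (no percent)."""
    out = zone_summary.copy()
    for col in ("loss_ha", "gain_ha", "net_ha"):
        out[col] = out[col].round(0).astype("int64")
    for col in ("loss_pct", "gain_pct"):
        out[col] = out[col].round(1)
    out = out.rename(
        columns={
            "zone": "Elevation zone (m)",
            "loss_ha": "Woody loss (ha)",
            "loss_pct": "% loss",
            "gain_ha": "Woody gain (ha)",
            "gain_pct": "% gain",
            "net_ha": "Net change (ha)",
        }
    )
    return out


def make_table3(akaike: pd.DataFrame, top: int = 4) -> pd.DataFrame:
    """Best-model summary: AIC to 2 decimals, weights to 3."""
    out = akaike.head(top)[["model", "aic", "delta_aic", "weight"]].copy()
    out["aic"] = out["aic"].round(2)
    out["delta_aic"] = out["delta_aic"].round(2)
    out["weight"] = out["weight"].round(3)
    return out.rename(
        columns={"model": "Model", "aic": "AIC", "delta_aic": "dAIC",
                 "weight": "Model weight"}
    )


def make_figure2_data(country_summary: pd.DataFrame) -> pd.DataFrame:
    """Per-country per-elevation-zone gain/loss bars with country nets in the
    panel labels (the data behind the country panels figure)."""
    out = country_summary.copy()
    out["panel"] = out.apply(
        lambda r: f"{r['country']} ({r['country_net_ha']:+,.0f} ha)", axis=1
    )
    return out[["panel", "country", "zone", "loss_ha", "gain_ha", "net_ha"]]
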