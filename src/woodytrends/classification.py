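"""Zone-specific supervised land-cover classification and accuracy assessment.

One Random Forest model is trained per mapping zone (zones follow the biome
delineations); training samples are paired with the feature vector of their
reference year, and the fitted zone models are applied to every year's
feature stack to produce 14 annual land-cover maps.  The analysis target is
the woody class (natural trees and shrubs); plantation is not counted as
woody by default, switchable for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .features import FEATURE_NAMES
from .synthetic import CLASS_CODES, CODE_NAMES

log = logging.getLogger(__name__)

OTHER_CODE = CLASS_CODES["other"]
WOODY_CODE = CLASS_CODES["woody"]
PLANTATION_CODE = CLASS_CODES["plantation"]


@dataclass
class ZoneModel:
    """A fitted classifier bound to its mapping zone and seed."""

    zone: str
    seed: int
    classes: tuple[str, ...]
    clf: RandomForestClassifier

    def save(self, path) -> None:
        """Persist the fitted model with its zone id and seed (joblib)."""
        import joblib

        joblib.dump({"zone": self.zone, "seed": self.seed,
                     "classes": self.classes, "clf": self.clf}, path)

    @classmethod
    def load(cls, path) -> "ZoneModel":
        import joblib

        return cls(**joblib.load(path))


def pair_samples(
    samples: pd.DataFrame, feature_tables: dict[int, pd.DataFrame]
) -> pd.DataFrame:
    """Join each training sample to the feature row of its reference year.

    ``samples`` needs columns pixel_id, label, year, zone;
    ``feature_tables`` maps year -> feature table indexed by pixel_id.
    Samples whose (pixel, year) row is missing or unusable are dropped with a
    logged count; duplicate (pixel, year, label) rows collapse to one.
    """
    samples = samples.drop_duplicates(subset=["pixel_id", "year", "label"])
    parts, dropped = [], 0
    for year, grp in samples.groupby("year"):
        table = feature_tables.get(year)
        if table is None:
            dropped += len(grp)
            continue
        ok = grp["pixel_id"].isin(table.index)
        if "usable" in table.columns:
            usable = table["usable"].reindex(grp["pixel_id"]).to_numpy()
            ok &= np.where(pd.isna(usable), False, usable).astype(bool)
        dropped += int((~ok).sum())
        grp = grp[ok]
        feats = table.loc[grp["pixel_id"], list(FEATURE_NAMES)].reset_index(drop=True)
        feats.insert(0, "label", grp["label"].to_numpy())
        feats.insert(1, "zone", grp["zone"].to_numpy())
        feats.insert(2, "pixel_id", grp["pixel_id"].to_numpy())
        feats.insert(3, "year", year)
        parts.append(feats)
    if dropped:
        log.info("pair_samples: dropped %d samples without usable features", dropped)
    if not parts:
        return pd.DataFrame(columns=["label", "zone", "pixel_id", "year", *FEATURE_NAMES])
    return pd.concat(parts, ignore_index=True)


def train_zone_model(
    training: pd.DataFrame,
    zone: str,
    n_estimators: int = 500,
    seed: int = 0,
    **rf_kwargs,
) -> ZoneModel:
    """Fit the zone's Random Forest on its own samples only."""
    sub = training[training["zone"] == zone]
    labels = sorted(sub["label"].unique())
    if len(labels) < 2:
        raise ValueError(
            f"zone {zone!r} has {len(labels)} class(es) in training data; need >= 2"
        )
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **rf_kwargs
    )
    X = sub[list(FEATURE_NAMES)].to_numpy(dtype=np.float32)
    y = sub["label"].to_numpy()
    clf.fit(X, y)
    return ZoneModel(zone=zone, seed=seed, classes=tuple(labels), clf=clf)


def classify_annual(
    features: pd.DataFrame,
    pixel_zone: np.ndarray,
    models: dict[str, ZoneModel],
    shape: tuple[int, int],
) -> np.ndarray:
    """Predict one year's land-cover map (integer class codes, row-major).

    Every pixel must fall in a zone that has a model.  Pixels without usable
    features are assigned the 'other' code (nodata-derived) and never woody.
    """
    n = shape[0] * shape[1]
    out = np.full(n, OTHER_CODE, dtype=np.uint8)
    usable = (
        features["usable"].to_numpy()
        if "usable" in features.columns
        else np.ones(n, dtype=bool)
    )
    X_all = features[list(FEATURE_NAMES)].to_numpy(dtype=np.float32)
    for zone in np.unique(pixel_zone):
        if zone not in models:
            raise KeyError(f"no model for mapping zone {zone!r}")
        sel = (pixel_zone == zone) & usable
        if not sel.any():
            continue
        pred = models[zone].clf.predict(X_all[sel])
        out[sel] = [CLASS_CODES[p] for p in pred]
    return out.reshape(shape)


def binarize_woody(lc_map: np.ndarray, include_plantation: bool = False) -> np.ndarray:
    """Boolean woody mask; plantation counts only when explicitly included."""
    mask = lc_map == WOODY_CODE
    if include_plantation:
        mask |= lc_map == PLANTATION_CODE
    return mask


@dataclass
class ConfusionMatrix:
    """Counts plus overall and per-class user/producer accuracies."""

    labels: tuple[str, ...]
    counts: np.ndarray
    overall: float = field(init=False)
    users: pd.Series = field(init=False)
    producers: pd.Series = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        total = c.sum()
        self.overall = float(np.trace(c) / total) if total else float("nan")
        with np.errstate(invalid="ignore", divide="ignore"):
            self.users = pd.Series(np.diag(c) / c.sum(axis=1), index=self.labels)
            self.producers = pd.Series(np.diag(c) / c.sum(axis=0), index=self.labels)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def assess_accuracy(
    predicted: np.ndarray, reference: np.ndarray
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Five-class and woody/non-woody confusion matrices for matched samples.

    ``predicted`` / ``reference`` are parallel arrays of integer class codes
    (e.g. map values at random reference pixels).  Fails on an empty set.
    """
    predicted = np.asarray(predicted).ravel()
    reference = np.asarray(reference).ravel()
    if predicted.size == 0:
        raise ValueError("empty reference sample set")
    codes = sorted(set(np.unique(reference)) | set(np.unique(predicted)))
    labels = tuple(CODE_NAMES[c] for c in codes)
    full = ConfusionMatrix(labels, _sk_confusion(reference, predicted, labels=codes))
    pw = binarize_woody(predicted).astype(int)
    rw = binarize_woody(reference).astype(int)
    woody = ConfusionMatrix(
        ("non-woody", "woody"), _sk_confusion(rw, pw, labels=[0, 1])
    )
    return full, woody
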