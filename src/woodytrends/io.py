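"""Readers/writers for the pipeline's file formats.

Rasters are plain TIFF (tifffile) with a JSON sidecar giving the planar
transform (origin, pixel size); vector layers are GeoJSON; tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape


def write_raster(path: str | Path, array: np.ndarray, pixel_size_m: float = 250.0):
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array))
    meta = {"origin": [0.0, 0.0], "pixel_size_m": pixel_size_m,
            "order": "row-major, row 0 = southernmost"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_geojson(path: str | Path, df: pd.DataFrame, geometry_col: str = "geometry"):
    feats = []
    for _, row in df.iterrows():
        props = {k: v for k, v in row.items() if k != geometry_col}
        props = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in props.items()}
        feats.append(
            {"type": "Feature", "geometry": mapping(row[geometry_col]),
             "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def read_geojson(path: str | Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        row = dict(feat["properties"])
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, manifest: dict):
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
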