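"""Hexagonal tessellation of the study region and per-hexagon woody-area accounting.

The analysis unit is a regular hexagon with flat edges facing north and
south, so its north-south extent equals the flat-to-flat width ``w`` and its
area is (sqrt(3)/2) * w**2.  The default width of 11.547 km gives cells of
115.47 km^2 (~11,547 ha).  Hexagons tile the plane without gaps or overlaps;
every raster-cell center is assigned to exactly one hexagon.

All coordinates are planar meters in an equal-area synthetic world; area
accounting, not geodesy, is what the downstream statistics consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

SQRT3 = math.sqrt(3.0)

#: nominal MODIS-like pixel area in hectares (250 m x 250 m)
PIXEL_AREA_HA = 6.25


def hexagon_area(flat_to_flat_km: float) -> float:
    """Area in km^2 of a regular hexagon with the given flat-to-flat width in km.

    area = (sqrt(3)/2) * w**2.  Raises ``ValueError`` for non-positive width.
    """
    if flat_to_flat_km <= 0:
        raise ValueError(f"hexagon width must be positive, got {flat_to_flat_km}")
    return (SQRT3 / 2.0) * flat_to_flat_km**2


@dataclass(frozen=True)
class HexGridSpec:
    """Lattice parameters for a flat-north/south hexagon grid.

    ``circumradius`` is the center-to-vertex distance R = w / sqrt(3);
    columns are spaced 1.5 R apart in x, rows w apart in y, and odd columns
    are shifted up by w/2 (the standard interlocking offset).
    """

    width_m: float
    origin_x: float
    origin_y: float

    @property
    def circumradius(self) -> float:
        return self.width_m / SQRT3

    @property
    def dx(self) -> float:
        return 1.5 * self.circumradius

    @property
    def dy(self) -> float:
        return self.width_m

    def center(self, col: np.ndarray, row: np.ndarray):
        x = self.origin_x + self.dx * col
        y = self.origin_y + self.dy * row + (np.asarray(col) % 2) * (self.dy / 2.0)
        return x, y

    def polygon(self, col: int, row: int) -> Polygon:
        # vertices lie on the half-lattice (multiples of R/2 in x, w/2 in y);
        # computing them as integer multiples makes shared vertices of
        # adjacent cells bitwise identical, so the tiling is watertight
        hx = self.circumradius / 2.0
        hy = self.width_m / 2.0
        kx = 3 * col
        ky = 2 * row + (col % 2)
        ks = [(kx + 2, ky), (kx + 1, ky + 1), (kx - 1, ky + 1),
              (kx - 2, ky), (kx - 1, ky - 1), (kx + 1, ky - 1)]
        return Polygon(
            [(self.origin_x + i * hx, self.origin_y + j * hy) for i, j in ks]
        )


def hex_id(col: int | np.ndarray, row: int | np.ndarray) -> np.ndarray:
    """Stable cell identifier; zero-padded so lexicographic order == (col, row)."""
    col = np.atleast_1d(np.asarray(col))
    row = np.atleast_1d(np.asarray(row))
    # columns/rows can be negative near the origin; offset keeps ids sortable
    return np.char.add(
        np.char.add("c", np.char.zfill((col + 500).astype(str), 4)),
        np.char.add("r", np.char.zfill((row + 500).astype(str), 4)),
    )


def make_hexgrid(
    extent: tuple[float, float, float, float],
    flat_to_flat_km: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Build the hexagon layer covering ``extent`` = (xmin, ymin, xmax, ymax) meters.

    Returns a DataFrame with columns ``hex_id, col, row, cx, cy, geometry,
    area_km2`` containing every cell whose polygon intersects the extent.
    The union of cells covers the extent completely; interiors are disjoint.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent}")
    width_m = flat_to_flat_km * 1000.0
    spec = HexGridSpec(width_m, origin[0], origin[1])
    if (xmax - xmin) < 2 * spec.circumradius and (ymax - ymin) < width_m:
        raise ValueError("extent too small to host at least one full hexagon")

    c_lo = math.floor((xmin - spec.circumradius - spec.origin_x) / spec.dx)
    c_hi = math.ceil((xmax + spec.circumradius - spec.origin_x) / spec.dx)
    r_lo = math.floor((ymin - width_m - spec.origin_y) / spec.dy)
    r_hi = math.ceil((ymax + width_m - spec.origin_y) / spec.dy)
    cols, rows = np.meshgrid(
        np.arange(c_lo, c_hi + 1), np.arange(r_lo, r_hi + 1), indexing="ij"
    )
    cols = cols.ravel()
    rows = rows.ravel()
    cx, cy = spec.center(cols, rows)

    # keep cells that can intersect the extent (bounding-circle test, then exact)
    near = (
        (cx >= xmin - spec.circumradius)
        & (cx <= xmax + spec.circumradius)
        & (cy >= ymin - width_m / 2.0 - 1e-9)
        & (cy <= ymax + width_m / 2.0 + 1e-9)
    )
    cols, rows, cx, cy = cols[near], rows[near], cx[near], cy[near]
    polys = [spec.polygon(c, r) for c, r in zip(cols, rows)]
    box = shapely.box(xmin, ymin, xmax, ymax)
    # positive-area overlap only: cells touching the extent at a lone vertex
    # or edge contribute no pixels and are not part of the cover
    keep = shapely.area(shapely.intersection(np.array(polys, dtype=object), box)) > 0

    df = pd.DataFrame(
        {
            "hex_id": hex_id(cols[keep], rows[keep]),
            "col": cols[keep],
            "row": rows[keep],
            "cx": cx[keep],
            "cy": cy[keep],
            "geometry": [p for p, k in zip(polys, keep) if k],
        }
    )
    df["area_km2"] = hexagon_area(flat_to_flat_km)
    df.attrs["spec"] = spec
    return df.sort_values("hex_id", ignore_index=True)


def assign_points(
    grid: pd.DataFrame, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Assign each point to exactly one hexagon of ``grid``; returns hex_id array.

    Uses the nearest-lattice-center rule, which for a regular hexagonal
    tessellation is exactly point-in-polygon; distance ties on shared edges
    resolve to the lexicographically smallest hex_id.  Points whose cell is
    not present in ``grid`` get the empty string.
    """
    spec: HexGridSpec = grid.attrs["spec"]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size

    c0 = np.round((x - spec.origin_x) / spec.dx).astype(np.int64)
    best_d = np.full(n, np.inf)
    best_c = np.zeros(n, dtype=np.int64)
    best_r = np.zeros(n, dtype=np.int64)
    for dc in (-1, 0, 1):
        c = c0 + dc
        yrel = (y - spec.origin_y - (c % 2) * (spec.dy / 2.0)) / spec.dy
        for r in (np.floor(yrel).astype(np.int64), np.ceil(yrel).astype(np.int64)):
            cx, cy = spec.center(c, r)
            d = (x - cx) ** 2 + (y - cy) ** 2
            # strict inequality with an epsilon tie-band; ties resolved below
            better = d < best_d - 1e-6
            tie = np.abs(d - best_d) <= 1e-6
            # lexicographic (col, row) order equals hex_id order
            tie_win = tie & (
                (c < best_c) | ((c == best_c) & (r < best_r))
            )
            upd = better | tie_win
            best_d[upd] = d[upd]
            best_c[upd] = c[upd]
            best_r[upd] = r[upd]

    ids = hex_id(best_c, best_r)
    known = pd.Index(grid["hex_id"])
    mask = known.get_indexer(ids) >= 0
    out = np.where(mask, ids, "")
    return out


def attach_attributes(
    grid: pd.DataFrame,
    dem: np.ndarray,
    cell_x: np.ndarray,
    cell_y: np.ndarray,
    countries: pd.DataFrame,
    biomes: pd.DataFrame,
) -> pd.DataFrame:
    """Enrich hexagons with median elevation, majority-area country, biome flags.

    ``dem`` is a 2-D elevation raster whose cell centers are given by the 1-D
    coordinate vectors ``cell_x`` (columns) / ``cell_y`` (rows).  Median
    elevation uses DEM cells whose centers fall inside the hexagon; country is
    the polygon with the largest overlap area; a biome flag is set for any
    non-empty intersection.  Hexagons containing no DEM cell get NaN elevation
    and are excluded downstream.
    """
    gx, gy = np.meshgrid(cell_x, cell_y)
    assigned = assign_points(grid, gx.ravel(), gy.ravel())
    elev = pd.Series(dem.ravel(), index=assigned)
    med = elev.groupby(level=0).median()
    med = med.reindex(grid["hex_id"]).to_numpy()

    geoms = np.array(grid["geometry"].tolist(), dtype=object)
    country = np.array([""] * len(grid), dtype=object)
    best_area = np.zeros(len(grid))
    for _, crow in countries.iterrows():
        inter = shapely.area(shapely.intersection(geoms, crow["geometry"]))
        win = inter > best_area
        country[win] = crow["name"]
        best_area[win] = inter[win]

    out = grid.copy()
    out["median_elev_m"] = med
    out["country"] = country
    for _, brow in biomes.iterrows():
        out[f"biome_{brow['name']}"] = shapely.intersects(geoms, brow["geometry"])
    out.attrs["spec"] = grid.attrs["spec"]
    return out


def filter_study_hexagons(
    enriched: pd.DataFrame, min_elevation_m: float = 1000.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep hexagons with median elevation >= 1,000 m intersecting >= 1 biome.

    Returns ``(study, excluded)``; ``excluded`` carries a ``reason`` column.
    """
    biome_cols = [c for c in enriched.columns if c.startswith("biome_")]
    elev_ok = enriched["median_elev_m"] >= min_elevation_m
    has_elev = enriched["median_elev_m"].notna()
    biome_ok = (
        enriched[biome_cols].any(axis=1) if biome_cols else pd.Series(False, index=enriched.index)
    )
    keep = has_elev & elev_ok & biome_ok
    reason = np.select(
        [~has_elev, ~elev_ok, ~biome_ok],
        ["no_dem_cells", "median_elevation_below_1000m", "no_biome_intersection"],
        default="",
    )
    excluded = enriched.loc[~keep].copy()
    excluded["reason"] = reason[~keep.to_numpy()]
    study = enriched.loc[keep].reset_index(drop=True)
    study.attrs["spec"] = enriched.attrs["spec"]
    return study, excluded


def woody_area_by_hexagon_year(
    woody_masks: dict[int, np.ndarray],
    study: pd.DataFrame,
    cell_x: np.ndarray,
    cell_y: np.ndarray,
    pixel_area_ha: float = PIXEL_AREA_HA,
) -> pd.DataFrame:
    """Sum woody pixel area (ha) per hexagon per year.

    ``woody_masks`` maps year -> boolean raster; pixel membership is by pixel
    center.  Returns a DataFrame indexed by hex_id with one column per year.
    """
    years = sorted(woody_masks)
    gx, gy = np.meshgrid(cell_x, cell_y)
    assigned = assign_points(study, gx.ravel(), gy.ravel())
    in_study = assigned != ""
    idx = pd.Index(study["hex_id"])
    pos = idx.get_indexer(assigned[in_study])
    out = np.zeros((len(study), len(years)))
    for j, yr in enumerate(years):
        mask = np.asarray(woody_masks[yr]).ravel()[in_study]
        out[:, j] = np.bincount(pos, weights=mask.astype(float), minlength=len(study))
    out *= pixel_area_ha
    df = pd.DataFrame(out, index=idx, columns=years)
    df.columns.name = "year"
    return df
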