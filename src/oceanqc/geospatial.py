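"""Spatial masking, the 0.1° analysis grid, and occupancy categories.

All geometry is geographic (WGS84, EPSG:4326); grid cells are squares in
degrees, so their metric area shrinks with latitude.  Masking follows the
order ridge → land → AOI: records south of the study region's bounding
ridge are removed first, then records on land, then anything left outside
the AOI polygon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

MASK_BUCKETS = ("no_coordinates", "south_of_ridge", "on_land", "outside_aoi")

#: occupancy categories: A = 1–10 inclusive, then left-open/right-closed
#: decade bins up to F = (1e5, 1e6].
CATEGORY_EDGES = (10, 100, 1_000, 10_000, 100_000, 1_000_000)
CATEGORY_LETTERS = ("A", "B", "C", "D", "E", "F")


@dataclass
class AOIMask:
    """Area-of-interest polygon plus the ridge and land exclusion masks.

    ``bbox`` is (lat_min, lat_max, lon_min, lon_max) and must contain the
    AOI polygon.  ``ridge_polygon`` masks the area south of the bounding
    ridge; ``land_polygons`` mask terrestrial points.  Either mask may be
    None (nothing excluded by that step).
    """

    aoi_polygon: BaseGeometry
    ridge_polygon: BaseGeometry | None = None
    land_polygons: BaseGeometry | None = None
    bbox: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("aoi_polygon", "ridge_polygon", "land_polygons"):
            geom = getattr(self, name)
            if geom is not None and not geom.is_valid:
                raise ValueError(f"invalid mask geometry: {name}")
        if self.bbox is None:
            lon0, lat0, lon1, lat1 = self.aoi_polygon.bounds
            self.bbox = (lat0, lat1, lon0, lon1)
        lat0, lat1, lon0, lon1 = self.bbox
        blo = box(lon0, lat0, lon1, lat1)
        if not blo.buffer(1e-9).covers(self.aoi_polygon):
            raise ValueError("aoi_polygon must lie within bbox")

    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for name in ("aoi_polygon", "ridge_polygon", "land_polygons"):
            geom = getattr(self, name)
            if geom is not None:
                feats.append(
                    {
                        "type": "Feature",
                        "properties": {"role": name},
                        "geometry": mapping(geom),
                    }
                )
        doc = {
            "type": "FeatureCollection",
            "bbox_latlon": list(self.bbox),
            "features": feats,
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AOIMask":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        geoms: dict[str, BaseGeometry] = {}
        for feat in doc["features"]:
            geoms[feat["properties"]["role"]] = shape(feat["geometry"])
        bbox = tuple(doc["bbox_latlon"]) if "bbox_latlon" in doc else None
        return cls(
            aoi_polygon=geoms["aoi_polygon"],
            ridge_polygon=geoms.get("ridge_polygon"),
            land_polygons=geoms.get("land_polygons"),
            bbox=bbox,
        )


def mask_to_marine_aoi(
    table: pd.DataFrame, mask: AOIMask
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Split a table into marine-AOI records and named exclusion buckets.

    Returns ``(retained, buckets)`` where buckets maps each of
    ``no_coordinates, south_of_ridge, on_land, outside_aoi`` to the rows it
    captured.  Retained rows plus all bucket rows partition the input.
    """
    lat = pd.to_numeric(table["decimalLatitude"], errors="coerce")
    lon = pd.to_numeric(table["decimalLongitude"], errors="coerce")
    has_coords = lat.notna() & lon.notna()

    buckets: dict[str, pd.DataFrame] = {}
    buckets["no_coordinates"] = table.loc[~has_coords]
    current = table.loc[has_coords]
    pts = shapely.points(lon[has_coords].to_numpy(), lat[has_coords].to_numpy())

    def split(geom: BaseGeometry | None, inside_is_excluded: bool) -> pd.DataFrame:
        nonlocal current, pts
        if geom is None:
            return current.iloc[0:0]
        shapely.prepare(geom)
        inside = shapely.covers(geom, pts)
        excl = inside if inside_is_excluded else ~inside
        dropped = current.loc[excl]
        current = current.loc[~excl]
        pts = pts[~excl]
        return dropped

    buckets["south_of_ridge"] = split(mask.ridge_polygon, True)
    buckets["on_land"] = split(mask.land_polygons, True)
    buckets["outside_aoi"] = split(mask.aoi_polygon, False)
    return current, buckets


@dataclass
class Grid:
    """Regular geographic grid of ``cell_size``-degree squares over the AOI.

    Cells are indexed ``cell_id = row * ncols + col`` with (row 0, col 0) at
    the bbox's south-west corner.  Only cells whose rectangle intersects the
    AOI polygon are members.  Cell membership of a point is half-open
    (``[lat0, lat0 + s)`` × ``[lon0, lon0 + s)``) with the bbox's top and
    right boundary closed, so every in-AOI point maps to exactly one cell.
    """

    lat_min: float
    lon_min: float
    cell_size: float
    nrows: int
    ncols: int
    cell_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(sorted(set(np.asarray(self.cell_ids).tolist())))
        self._members = frozenset(int(c) for c in self.cell_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cell_size

    def point_to_cell(self, lat, lon) -> np.ndarray:
        """Raw (pre-membership) cell id of each point; -1 outside the bbox."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        row = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row[lat == self.lat_max] = self.nrows - 1   # closed top boundary
        col[lon == self.lon_max] = self.ncols - 1   # closed right boundary
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        ok &= np.isfinite(lat) & np.isfinite(lon)
        out = np.where(ok, row * self.ncols + col, -1)
        return out

    def cell_box(self, cell_id: int):
        row, col = divmod(int(cell_id), self.ncols)
        lat0 = self.lat_min + row * self.cell_size
        lon0 = self.lon_min + col * self.cell_size
        return box(lon0, lat0, lon0 + self.cell_size, lat0 + self.cell_size)

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"cell_id": int(cid)},
                "geometry": mapping(self.cell_box(cid)),
            }
            for cid in self.cell_ids
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}),
            encoding="utf-8",
        )


def build_grid(mask: AOIMask, cell_size: float = 0.1) -> Grid:
    """Tile the AOI bbox with ``cell_size``-degree cells; keep those
    intersecting the AOI polygon.  Cell ids are deterministic functions of
    the bbox origin."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    lat0, lat1, lon0, lon1 = mask.bbox
    nrows = math.ceil(round((lat1 - lat0) / cell_size, 9))
    ncols = math.ceil(round((lon1 - lon0) / cell_size, 9))
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    boxes = shapely.box(
        lon0 + cols * cell_size,
        lat0 + rows * cell_size,
        lon0 + (cols + 1) * cell_size,
        lat0 + (rows + 1) * cell_size,
    )
    shapely.prepare(mask.aoi_polygon)
    hit = shapely.intersects(mask.aoi_polygon, boxes)
    ids = rows[hit] * ncols + cols[hit]
    return Grid(
        lat_min=lat0,
        lon_min=lon0,
        cell_size=cell_size,
        nrows=nrows,
        ncols=ncols,
        cell_ids=ids,
    )


def assign_cells(table: pd.DataFrame, grid: Grid) -> pd.Series:
    """Cell id per record (nullable Int64); <NA> where the point falls in no
    grid cell (outside the bbox or in a cell that does not intersect the
    AOI).  Such records are excluded from spatial summaries."""
    lat = pd.to_numeric(table["decimalLatitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(table["decimalLongitude"], errors="coerce").to_numpy()
    raw = grid.point_to_cell(lat, lon)
    member = np.isin(raw, grid.cell_ids)
    out = pd.array(raw, dtype="Int64")
    out[~member] = pd.NA
    return pd.Series(out, index=table.index, name="cell_id")


def categorize_count(n: int) -> str | None:
    """Logarithmic occupancy category of a per-cell occurrence count.

    A = 1–10 (inclusive), then left-open/right-closed powers of ten:
    B = (10, 10²], …, F = (10⁵, 10⁶].  A count of 0 has no category.
    """
    n = int(n)
    if n < 0:
        raise ValueError("count must be non-negative")
    if n == 0:
        return None
    if n > CATEGORY_EDGES[-1]:
        raise ValueError(f"count {n} exceeds the largest category bound")
    for letter, hi in zip(CATEGORY_LETTERS, CATEGORY_EDGES):
        if n <= hi:
            return letter
    raise AssertionError("unreachable")


def category_histogram(
    cell_counts: pd.Series | dict[int, int]
) -> dict[str, int]:
    """Number of grid cells per occupancy category for one stratum.

    ``cell_counts`` maps cell_id → occurrence count; zero-count cells are
    not represented (a count of 0 has no category).
    """
    if isinstance(cell_counts, dict):
        cell_counts = pd.Series(cell_counts, dtype=int)
    hist: dict[str, int] = {}
    for n in cell_counts:
        letter = categorize_count(n)
        if letter is not None:
            hist[letter] = hist.get(letter, 0) + 1
    return {k: hist[k] for k in CATEGORY_LETTERS if k in hist}
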