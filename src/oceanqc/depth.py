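"""Two-part depth analysis: contour-based and raster-based classification.

Contour analysis assigns every in-AOI record to the shallow (< 500 m
seafloor) or deep (>= 500 m seafloor) dataset from the 500-m depth-zone
polygons derived from the bathymetry, and flags records whose recorded
depth (>= 500 m) contradicts a shallow location as possibly misplaced
(``shallowFromDeepSet``; excluded downstream).  Points covered by no zone
polygon — in practice coastal points where vector and raster coastlines
disagree — fall back into the shallow dataset.

Raster analysis splits depth-bearing records into planktonic
(``tiffPlankton``: recorded depth above the seafloor), benthic
(``tiffBenthos``: at the seafloor within a tolerance) and below-seafloor
(``tiffBelowDepth``: deeper than the seafloor; excluded downstream) by
comparing the recorded depth with the depth stored in the raster pixel
containing the record's coordinates.  The tolerance is the record's own
depthAccuracy when recorded, else a configurable default, applied
symmetrically.  Records over no raster pixel get ``noRasterCoverage`` and
stay in the main datasets but not in the planktonic/benthic sub-datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .raster import BathymetryGrid

MATCH_SHALLOW = "matchShallow"
MATCH_DEEP = "matchDeep"
SHALLOW_FROM_DEEP = "shallowFromDeepSet"
TIFF_PLANKTON = "tiffPlankton"
TIFF_BENTHOS = "tiffBenthos"
TIFF_BELOW_DEPTH = "tiffBelowDepth"
NO_RASTER_COVERAGE = "noRasterCoverage"

SHALLOW_DEEP_BOUNDARY = 500.0
MAX_ZONE = 11  # zones 1..11 tile 500 m .. 5569 m (Molloydypet)
MAX_DEPTH = 5569.0

#: oceanic provinces, lower bound inclusive, partitioning [0, 6000)
PROVINCE_EDGES = (0.0, 200.0, 1000.0, 4000.0, 6000.0)
PROVINCE_NAMES = (
    "sublittoral/epipelagic",
    "sublittoral-bathyal/mesopelagic",
    "bathyal/bathypelagic",
    "abyssal/abyssopelagic",
)


@dataclass
class DepthZoneSet:
    """500-m depth-zone polygons derived from the bathymetry raster.

    ``zones`` maps zone index → merged polygon; zone 0 is the shallow
    dataset area (< 500 m seafloor), zones 1..11 the deep dataset slices.
    Zones are disjoint and union to the raster's marine extent.
    """

    zones: dict[int, BaseGeometry]
    interval: float = 500.0

    def locate(self, lat, lon) -> np.ndarray:
        """Zone index containing each point, or -1 for no coverage.

        Zones are scanned shallow-first; a point exactly on a shared
        boundary therefore resolves to the shallower zone,
        deterministically.
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        pts = shapely.points(lon, lat)
        out = np.full(len(pts), -1, dtype=int)
        todo = np.ones(len(pts), dtype=bool)
        for z in sorted(self.zones):
            if not todo.any():
                break
            geom = self.zones[z]
            shapely.prepare(geom)
            hit = np.zeros(len(pts), dtype=bool)
            hit[todo] = shapely.covers(geom, pts[todo])
            out[hit] = z
            todo &= ~hit
        return out


def derive_zone_polygons(
    bathy: BathymetryGrid, interval: float = 500.0
) -> DepthZoneSet:
    """Polygonize the classed bathymetry: each marine pixel joins zone
    ``floor(depth / interval)`` (capped at 11 for the 500-m interval), and
    same-zone pixels are merged into polygons.

    Pixel rectangles are merged row-wise into run-length boxes before the
    union, which keeps the construction exact (no simplification) while
    staying fast on fine grids.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    zclass = np.full(bathy.depth.shape, -1, dtype=int)
    marine = np.isfinite(bathy.depth)
    zclass[marine] = np.minimum(
        np.floor(bathy.depth[marine] / interval).astype(int), MAX_ZONE
    )
    if not marine.any():
        import warnings

        warnings.warn("bathymetry raster has no marine pixels; empty zone set")
        return DepthZoneSet(zones={}, interval=interval)

    cs = bathy.cellsize
    boxes_by_zone: dict[int, list] = {}
    for r in range(bathy.nrows):
        row = zclass[r]
        # run-length encode the row into (start, stop, zone) segments
        change = np.flatnonzero(np.diff(row)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [len(row)]))
        lat_top = bathy.lat_max - r * cs
        for a, b in zip(starts, stops):
            z = int(row[a])
            if z < 0:
                continue
            boxes_by_zone.setdefault(z, []).append(
                shapely.box(
                    bathy.lon_min + a * cs,
                    lat_top - cs,
                    bathy.lon_min + b * cs,
                    lat_top,
                )
            )
    zones = {z: unary_union(bxs) for z, bxs in sorted(boxes_by_zone.items())}
    return DepthZoneSet(zones=zones, interval=interval)


def classify_contour(table: pd.DataFrame, zones: DepthZoneSet) -> pd.Series:
    """matchContour label per record.

    Rules: location in zone 0 → ``matchShallow`` unless the recorded depth
    is >= 500 m, which contradicts the shallow location and yields
    ``shallowFromDeepSet``; location in zones 1–11 → ``matchDeep`` (with or
    without recorded depth); no zone coverage → ``matchShallow`` (coastal
    fallback).
    """
    lat = pd.to_numeric(table["decimalLatitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(table["decimalLongitude"], errors="coerce").to_numpy()
    depth = pd.to_numeric(table.get("depth"), errors="coerce").to_numpy()
    zone = zones.locate(lat, lon)
    out = np.where(zone >= 1, MATCH_DEEP, MATCH_SHALLOW).astype(object)
    misplaced = (zone == 0) & np.isfinite(depth) & (depth >= SHALLOW_DEEP_BOUNDARY)
    out[misplaced] = SHALLOW_FROM_DEEP
    return pd.Series(out, index=table.index, name="matchContour")


def classify_raster(
    table: pd.DataFrame,
    bathy: BathymetryGrid,
    default_tolerance: float = 10.0,
) -> pd.Series:
    """tiffmatch label per depth-bearing record (NA where depth is missing).

    With s the seafloor depth in the pixel containing the record, d the
    recorded depth and τ the record's depthAccuracy (or the default):
    d < s − τ → ``tiffPlankton``; |d − s| ≤ τ → ``tiffBenthos``;
    d > s + τ → ``tiffBelowDepth``; no pixel → ``noRasterCoverage``.
    """
    if default_tolerance < 0:
        raise ValueError("default_tolerance must be non-negative")
    lat = pd.to_numeric(table["decimalLatitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(table["decimalLongitude"], errors="coerce").to_numpy()
    d = pd.to_numeric(table.get("depth"), errors="coerce").to_numpy(dtype=float)
    tau = pd.to_numeric(table.get("depthAccuracy"), errors="coerce").to_numpy(
        dtype=float
    )
    if np.nanmin(tau, initial=0.0) < 0:
        raise ValueError("depthAccuracy must be non-negative")
    tau = np.where(np.isfinite(tau), tau, default_tolerance)
    s = bathy.sample(lat, lon)
    out = np.full(len(table), None, dtype=object)
    has_depth = np.isfinite(d)
    covered = np.isfinite(s)
    out[has_depth & ~covered] = NO_RASTER_COVERAGE
    m = has_depth & covered
    out[m & (d < s - tau)] = TIFF_PLANKTON
    out[m & (np.abs(d - s) <= tau)] = TIFF_BENTHOS
    out[m & (d > s + tau)] = TIFF_BELOW_DEPTH
    return pd.Series(out, index=table.index, name="tiffmatch")


def assign_depth_zone(depth) -> np.ndarray | int:
    """500-m depth zone index: 0 for depths < 500 m (the shallow dataset),
    else ``min(floor(depth / 500), 11)`` (zones 1–11, the deep dataset).

    Depths outside [0, 5569] raise — deeper values are depth outliers and
    must be removed by the QC stage before zones are assigned.
    """
    arr = np.atleast_1d(np.asarray(depth, dtype=float))
    finite = arr[np.isfinite(arr)]
    if ((finite < 0) | (finite > MAX_DEPTH)).any():
        raise ValueError(f"depth outside [0, {MAX_DEPTH}] — depth outlier")
    zone = np.minimum(
        np.floor(arr / SHALLOW_DEEP_BOUNDARY), MAX_ZONE
    )
    zone = np.where(arr < SHALLOW_DEEP_BOUNDARY, 0, zone)
    if np.isscalar(depth) or np.asarray(depth).ndim == 0:
        return int(zone[0])
    return zone


def assign_province(depth) -> np.ndarray | str:
    """Oceanic province of a depth, lower bound inclusive:
    sublittoral/epipelagic [0, 200), sublittoral-bathyal/mesopelagic
    [200, 1000), bathyal/bathypelagic [1000, 4000),
    abyssal/abyssopelagic [4000, 6000)."""
    arr = np.atleast_1d(np.asarray(depth, dtype=float))
    if ((arr < PROVINCE_EDGES[0]) | (arr >= PROVINCE_EDGES[-1])).any():
        raise ValueError(f"depth outside [0, {PROVINCE_EDGES[-1]})")
    idx = np.searchsorted(PROVINCE_EDGES, arr, side="right") - 1
    names = np.asarray(PROVINCE_NAMES, dtype=object)[idx]
    if np.isscalar(depth) or np.asarray(depth).ndim == 0:
        return str(names[0])
    return names
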