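import numpy as np
import pandas as pd
import pytest

from oceanqc.depth import (
    assign_depth_zone,
    assign_province,
    classify_contour,
    classify_raster,
    derive_zone_polygons,
)
from oceanqc.raster import BathymetryGrid
from tests.conftest import make_table


def brute_force_contour(bathy, lat, lon, depth):
    """Independent per-point classifier scanning the raw raster directly.

    Finds the containing pixel by comparing the point against explicit
    pixel-edge arrays, then applies the classification rules on the stored
    seafloor depth — no polygons, no shared lookup code.
    """
    lat_edges = bathy.lat_min + np.arange(bathy.nrows + 1) * bathy.cellsize
    lon_edges = bathy.lon_min + np.arange(bathy.ncols + 1) * bathy.cellsize
    out = []
    for la, lo, d in zip(lat, lon, depth):
        s = np.nan
        if lat_edges[0] <= la <= lat_edges[-1] and lon_edges[0] <= lo <= lon_edges[-1]:
            i = int(np.searchsorted(lat_edges, la, side="right")) - 1
            j = int(np.searchsorted(lon_edges, lo, side="right")) - 1
            i, j = min(i, bathy.nrows - 1), min(j, bathy.ncols - 1)
            s = bathy.depth[bathy.nrows - 1 - i, j]   # row 0 is north
        if np.isnan(s):
            out.append("matchShallow")      # coastal fallback
        elif s >= 500.0:
            out.append("matchDeep")
        elif np.isfinite(d) and d >= 500.0:
            out.append("shallowFromDeepSet")
        else:
            out.append("matchShallow")
    return out


def brute_force_raster(bathy, lat, lon, depth, acc, default_tol):
    lat_edges = bathy.lat_min + np.arange(bathy.nrows + 1) * bathy.cellsize
    lon_edges = bathy.lon_min + np.arange(bathy.ncols + 1) * bathy.cellsize
    out = []
    for la, lo, d, a in zip(lat, lon, depth, acc):
        if not np.isfinite(d):
            out.append(None)
            continue
        s = np.nan
        if lat_edges[0] <= la <= lat_edges[-1] and lon_edges[0] <= lo <= lon_edges[-1]:
            i = int(np.searchsorted(lat_edges, la, side="right")) - 1
            j = int(np.searchsorted(lon_edges, lo, side="right")) - 1
            i, j = min(i, bathy.nrows - 1), min(j, bathy.ncols - 1)
            s = bathy.depth[bathy.nrows - 1 - i, j]
        tau = a if np.isfinite(a) else default_tol
        if np.isnan(s):
            out.append("noRasterCoverage")
        elif d < s - tau:
            out.append("tiffPlankton")
        elif d > s + tau:
            out.append("tiffBelowDepth")
        else:
            out.append("tiffBenthos")
    return out


@pytest.fixture()
def two_level():
    # west half 800 m, east half 300 m, over lat [60,61], lon [0,2]
    depth = np.full((10, 20), 800.0)
    depth[:, 10:] = 300.0
    return BathymetryGrid(depth=depth, lat_min=60.0, lon_min=0.0, cellsize=0.1)


class TestZonePolygons:
    def test_two_level_seafloor_gives_two_zones(self, two_level):
        zones = derive_zone_polygons(two_level)
        assert set(zones.zones) == {0, 1}

    def test_depth_exactly_500_is_zone_1(self):
        grid = BathymetryGrid(
            depth=np.full((2, 2), 500.0), lat_min=0, lon_min=0, cellsize=1.0
        )
        zones = derive_zone_polygons(grid)
        assert set(zones.zones) == {1}

    def test_zones_partition_marine_area(self, bathy):
        zones = derive_zone_polygons(bathy)
        marine_area = np.isfinite(bathy.depth).sum() * bathy.cellsize**2
        total = sum(g.area for g in zones.zones.values())
        assert total == pytest.approx(marine_area, rel=1e-9)
        for a in zones.zones:
            for b in zones.zones:
                if a < b:
                    inter = zones.zones[a].intersection(zones.zones[b]).area
                    assert inter == pytest.approx(0.0, abs=1e-12)

    def test_all_land_raster_warns_and_returns_empty(self):
        grid = BathymetryGrid(
            depth=np.full((2, 2), np.nan), lat_min=0, lon_min=0, cellsize=1.0
        )
        with pytest.warns(UserWarning):
            zones = derive_zone_polygons(grid)
        assert zones.zones == {}

    def test_nonpositive_interval_rejected(self, two_level):
        with pytest.raises(ValueError):
            derive_zone_polygons(two_level, interval=0)


class TestClassifyContour:
    def test_rules(self, two_level):
        zones = derive_zone_polygons(two_level)
        table = make_table(
            decimalLatitude=[60.5] * 5,
            decimalLongitude=[1.5, 1.5, 1.5, 0.5, 0.5],
            depth=[np.nan, 800.0, 100.0, np.nan, 100.0],
        )
        got = classify_contour(table, zones).tolist()
        assert got == [
            "matchShallow",        # no depth over 300-m seafloor
            "shallowFromDeepSet",  # 800 m recorded over 300-m seafloor
            "matchShallow",        # 100 m over 300-m seafloor
            "matchDeep",           # no depth over 800-m seafloor
            "matchDeep",           # recorded depth over deep seafloor
        ]

    def test_coastal_fallback(self, two_level):
        zones = derive_zone_polygons(two_level)
        table = make_table(
            decimalLatitude=[59.0], decimalLongitude=[1.0], depth=[100.0]
        )
        assert classify_contour(table, zones).iloc[0] == "matchShallow"


class TestClassifyRaster:
    def test_plankton_benthos_below(self):
        grid = BathymetryGrid(
            depth=np.full((2, 2), 1000.0), lat_min=0, lon_min=0, cellsize=1.0
        )
        table = make_table(
            decimalLatitude=[0.5] * 3,
            decimalLongitude=[0.5] * 3,
            depth=[100.0, 1000.0, 1100.0],
            depthAccuracy=[0.0, np.nan, 10.0],
        )
        got = classify_raster(table, grid, default_tolerance=10.0).tolist()
        assert got == ["tiffPlankton", "tiffBenthos", "tiffBelowDepth"]

    def test_no_coverage_and_missing_depth(self):
        grid = BathymetryGrid(
            depth=np.full((2, 2), 1000.0), lat_min=0, lon_min=0, cellsize=1.0
        )
        table = make_table(
            decimalLatitude=[5.0, 0.5],
            decimalLongitude=[0.5, 0.5],
            depth=[100.0, np.nan],
        )
        got = classify_raster(table, grid, 10.0)
        assert got.iloc[0] == "noRasterCoverage"
        assert got.iloc[1] is None

    def test_negative_tolerance_rejected(self):
        grid = BathymetryGrid(
            depth=np.full((2, 2), 1000.0), lat_min=0, lon_min=0, cellsize=1.0
        )
        table = make_table(decimalLatitude=[0.5], decimalLongitude=[0.5], depth=[1.0])
        with pytest.raises(ValueError):
            classify_raster(table, grid, default_tolerance=-1.0)
        with pytest.raises(ValueError):
            classify_raster(
                table.assign(depthAccuracy=[-5.0]), grid, default_tolerance=1.0
            )


class TestDepthZone:
    @pytest.mark.parametrize(
        "depth, zone",
        [(0.0, 0), (499.9, 0), (500.0, 1), (999.9, 1), (1000.0, 2), (5569.0, 11)],
    )
    def test_boundaries(self, depth, zone):
        assert assign_depth_zone(depth) == zone

    def test_outlier_depth_raises(self):
        with pytest.raises(ValueError):
            assign_depth_zone(5570.0)
        with pytest.raises(ValueError):
            assign_depth_zone(-1.0)


class TestProvince:
    @pytest.mark.parametrize(
        "depth, name",
        [
            (0.0, "sublittoral/epipelagic"),
            (199.9, "sublittoral/epipelagic"),
            (200.0, "sublittoral-bathyal/mesopelagic"),
            (1000.0, "bathyal/bathypelagic"),
            (4500.0, "abyssal/abyssopelagic"),
        ],
    )
    def test_lower_inclusive_bins(self, depth, name):
        assert assign_province(depth) == name

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_province(6000.0)
        with pytest.raises(ValueError):
            assign_province(-0.1)


class TestOracleEquivalence:
    def test_contour_and_raster_match_brute_force(self, small_config, bathy):
        rng = np.random.default_rng(4242)
        n = 10_000
        lat0, lat1, lon0, lon1 = small_config.aoi_bounds
        lat = rng.uniform(lat0 - 0.2, lat1 + 0.2, n)
        lon = rng.uniform(lon0 - 0.2, lon1 + 0.2, n)
        depth = np.where(rng.random(n) < 0.3, np.nan, rng.uniform(0, 6000, n))
        acc = np.where(rng.random(n) < 0.5, np.nan, rng.uniform(0, 50, n))
        table = make_table(
            decimalLatitude=lat, decimalLongitude=lon, depth=depth, depthAccuracy=acc
        )
        zones = derive_zone_polygons(bathy)
        got_contour = classify_contour(table, zones).tolist()
        want_contour = brute_force_contour(bathy, lat, lon, depth)
        assert got_contour == want_contour
        got_raster = classify_raster(table, bathy, 10.0).tolist()
        want_raster = brute_force_raster(bathy, lat, lon, depth, acc, 10.0)
        assert got_raster == want_raster

    def test_benthos_over_deep_seafloor_is_match_deep(self, bathy):
        rng = np.random.default_rng(7)
        n = 2_000
        lat = rng.uniform(60.1, 63.9, n)
        lon = rng.uniform(0.1, 7.3, n)
        s = bathy.sample(lat, lon)
        table = make_table(
            decimalLatitude=lat, decimalLongitude=lon, depth=s, depthAccuracy=1.0
        )
        zones = derive_zone_polygons(bathy)
        contour = classify_contour(table, zones)
        raster = classify_raster(table, bathy, 1.0)
        benthos_deep = (raster == "tiffBenthos") & (s >= 500.0)
        assert (contour[benthos_deep] == "matchDeep").all()
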