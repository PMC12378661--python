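import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from oceanqc.geospatial import (
    AOIMask,
    assign_cells,
    build_grid,
    categorize_count,
    category_histogram,
    mask_to_marine_aoi,
)
from tests.conftest import make_table


@pytest.fixture()
def square_mask():
    return AOIMask(
        aoi_polygon=box(0.0, 56.0, 1.0, 57.0),
        ridge_polygon=box(0.0, 56.0, 1.0, 56.2),
        land_polygons=box(0.8, 56.2, 1.0, 57.0),
    )


class TestMasking:
    def test_buckets_capture_each_anomaly(self, square_mask):
        table = make_table(
            decimalLatitude=[56.5, 56.1, 56.5, 50.0, np.nan],
            decimalLongitude=[0.4, 0.4, 0.9, 0.5, 0.5],
        )
        retained, buckets = mask_to_marine_aoi(table, square_mask)
        assert len(retained) == 1
        assert buckets["south_of_ridge"].record_id.tolist() == ["r1"]
        assert buckets["on_land"].record_id.tolist() == ["r2"]
        assert buckets["outside_aoi"].record_id.tolist() == ["r3"]
        assert buckets["no_coordinates"].record_id.tolist() == ["r4"]

    def test_bucket_conservation(self, square_mask, synth, masks):
        occ, _ = synth
        retained, buckets = mask_to_marine_aoi(occ, masks)
        assert len(retained) + sum(len(b) for b in buckets.values()) == len(occ)

    def test_ridge_applied_before_land(self, square_mask):
        # a point both south of the ridge and on land goes to the ridge
        # bucket: the masks apply in that order
        mask = AOIMask(
            aoi_polygon=box(0, 56, 1, 57),
            ridge_polygon=box(0, 56, 1, 56.5),
            land_polygons=box(0, 56, 1, 57),
        )
        table = make_table(decimalLatitude=[56.2], decimalLongitude=[0.5])
        _, buckets = mask_to_marine_aoi(table, mask)
        assert len(buckets["south_of_ridge"]) == 1
        assert len(buckets["on_land"]) == 0

    def test_invalid_mask_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid"):
            AOIMask(aoi_polygon=box(0, 0, 1, 1), ridge_polygon=bowtie)

    def test_aoi_must_lie_within_bbox(self):
        with pytest.raises(ValueError, match="bbox"):
            AOIMask(aoi_polygon=box(0, 0, 2, 2), bbox=(0.0, 1.0, 0.0, 1.0))

    def test_geojson_round_trip(self, tmp_path, square_mask):
        path = tmp_path / "m.geojson"
        square_mask.to_geojson(path)
        back = AOIMask.from_geojson(path)
        assert back.aoi_polygon.equals(square_mask.aoi_polygon)
        assert back.ridge_polygon.equals(square_mask.ridge_polygon)
        assert back.bbox == square_mask.bbox


class TestGrid:
    def test_rectangular_aoi_cell_count(self):
        mask = AOIMask(aoi_polygon=box(0, 56, 1, 57))
        assert build_grid(mask, 0.1).n_cells == 100
        assert build_grid(mask, 0.5).n_cells == 4

    def test_l_shaped_aoi_matches_brute_force(self):
        l_shape = box(0, 56, 1, 56.5).union(box(0, 56.5, 0.5, 57))
        mask = AOIMask(aoi_polygon=l_shape, bbox=(56.0, 57.0, 0.0, 1.0))
        grid = build_grid(mask, 0.1)
        brute = sum(
            l_shape.intersects(box(c * 0.1, 56 + r * 0.1, (c + 1) * 0.1, 56 + (r + 1) * 0.1))
            for r in range(10)
            for c in range(10)
        )
        assert grid.n_cells == brute
        # interior cells: 10x5 lower block + 5x5 upper block, plus the
        # boundary row of upper cells that merely touch the lower block edge
        assert grid.n_cells >= 75

    def test_nonpositive_cell_size_rejected(self):
        mask = AOIMask(aoi_polygon=box(0, 56, 1, 57))
        with pytest.raises(ValueError):
            build_grid(mask, 0.0)

    def test_deterministic_cell_ids(self):
        mask = AOIMask(aoi_polygon=box(0, 56, 1, 57))
        a, b = build_grid(mask, 0.1), build_grid(mask, 0.1)
        np.testing.assert_array_equal(a.cell_ids, b.cell_ids)


class TestAssignCells:
    def test_interior_edge_point_goes_north_east(self):
        # 0.25-degree cells have binary-exact edges, so the point sits
        # exactly on the shared corner of four cells; the half-open rule
        # must put it in the single cell to the north-east
        grid = build_grid(AOIMask(aoi_polygon=box(0, 56, 1, 57)), 0.25)
        table = make_table(decimalLatitude=[56.5], decimalLongitude=[0.5])
        cells = assign_cells(table, grid)
        assert cells.notna().all()
        assert cells.iloc[0] == 2 * grid.ncols + 2

    def test_aoi_top_right_boundary_closed(self):
        grid = build_grid(AOIMask(aoi_polygon=box(0, 56, 1, 57)), 0.1)
        table = make_table(decimalLatitude=[57.0], decimalLongitude=[1.0])
        cell = assign_cells(table, grid).iloc[0]
        assert cell == 9 * grid.ncols + 9

    def test_counts_per_cell(self):
        grid = build_grid(AOIMask(aoi_polygon=box(0, 56, 1, 57)), 0.1)
        table = make_table(
            decimalLatitude=[56.05, 56.05, 56.06, 56.95],
            decimalLongitude=[0.05, 0.06, 0.05, 0.95],
        )
        cells = assign_cells(table, grid)
        counts = cells.value_counts()
        assert counts.loc[0] == 3
        assert counts.loc[9 * grid.ncols + 9] == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_every_uniform_point_assigned_exactly_once(self, seed):
        grid = build_grid(AOIMask(aoi_polygon=box(0, 56, 2, 57)), 0.1)
        rng = np.random.default_rng(seed)
        n = 200
        table = make_table(
            decimalLatitude=rng.uniform(56, 57, n),
            decimalLongitude=rng.uniform(0, 2, n),
        )
        cells = assign_cells(table, grid)
        assert cells.notna().all()
        assert cells.value_counts().sum() == n


class TestCategories:
    @pytest.mark.parametrize(
        "n, letter",
        [
            (1, "A"), (5, "A"), (10, "A"),
            (11, "B"), (100, "B"), (101, "C"),
            (1_000, "C"), (1_001, "D"), (10_000, "D"),
            (10_001, "E"), (100_000, "E"),
            (100_001, "F"), (1_000_000, "F"),
        ],
    )
    def test_boundary_sweep(self, n, letter):
        assert categorize_count(n) == letter

    def test_zero_has_no_category(self):
        assert categorize_count(0) is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            categorize_count(-1)
        with pytest.raises(ValueError):
            categorize_count(1_000_001)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(1, 1_000_000))
    def test_categories_partition_positive_counts(self, n):
        letter = categorize_count(n)
        lo = {"A": 1, "B": 11, "C": 101, "D": 1_001, "E": 10_001, "F": 100_001}
        hi = {"A": 10, "B": 100, "C": 1_000, "D": 10_000, "E": 100_000, "F": 1_000_000}
        assert lo[letter] <= n <= hi[letter]

    def test_histogram(self):
        assert category_histogram({1: 3, 2: 7, 3: 40}) == {"A": 2, "B": 1}
        assert category_histogram({}) == {}
        assert category_histogram({1: 0, 2: 5}) == {"A": 1}
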