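import numpy as np
import pytest

from nicheforge import (EARTH_RADIUS_KM, RasterGrid, binarize, cell_area_km2,
                        change_map, lowest_presence_threshold, percent_change,
                        summarize_change, total_area_km2)
from nicheforge.change import ABSENT, GAINED, LOST, STABLE, BinaryRangeRaster
from nicheforge.ensemble import ConsensusRaster
from nicheforge.occurrences import PresenceCells

from oracles import spherical_cell_area_quad


def _consensus(values, cell=0.5, west=0.0, south=0.0):
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    grid = RasterGrid(rows, cols, west=west, south=south,
                      east=west + cols * cell, north=south + rows * cell)
    return ConsensusRaster(grid=grid, values=values, member_count=1, weight_sum=1.0)


def _binary(values, cell=0.5, west=0.0, south=0.0):
    c = _consensus(values, cell=cell, west=west, south=south)
    return BinaryRangeRaster(grid=c.grid, values=c.values, threshold_used=0.5)


class TestLpt:
    def test_minimum_over_presence_cells(self):
        cons = _consensus([[0.31, 0.55], [0.72, 0.9]])
        pres = PresenceCells(grid=cons.grid, cells=np.array([0, 1, 2]))
        assert lowest_presence_threshold(cons, pres) == pytest.approx(0.31)

    def test_single_cell(self):
        cons = _consensus([[0.4, 0.9]])
        pres = PresenceCells(grid=cons.grid, cells=np.array([1]))
        assert lowest_presence_threshold(cons, pres) == pytest.approx(0.9)

    def test_presence_on_nodata_raises(self):
        cons = _consensus([[np.nan, 0.5]])
        pres = PresenceCells(grid=cons.grid, cells=np.array([0]))
        with pytest.raises(ValueError):
            lowest_presence_threshold(cons, pres)

    def test_binarization_at_lpt_covers_all_occurrences(self):
        rng = np.random.default_rng(0)
        cons = _consensus(rng.uniform(size=(10, 10)))
        pres = PresenceCells(grid=cons.grid, cells=rng.choice(100, size=20, replace=False))
        lpt = lowest_presence_threshold(cons, pres)
        binary = binarize(cons, lpt)
        assert np.all(binary.values.ravel()[pres.cells] == 1.0)


class TestBinarize:
    def test_inclusive_at_threshold(self):
        binary = binarize(_consensus([[0.5, 0.49]]), 0.5)
        np.testing.assert_array_equal(binary.values, [[1.0, 0.0]])

    def test_threshold_above_max_all_zero(self):
        binary = binarize(_consensus([[0.2, 0.8]]), 0.9)
        assert binary.values.sum() == 0.0

    def test_zero_threshold_all_ones(self):
        binary = binarize(_consensus([[0.2, 0.8]]), 0.0)
        assert binary.values.sum() == 2.0

    def test_nodata_preserved(self):
        binary = binarize(_consensus([[np.nan, 0.8]]), 0.5)
        assert np.isnan(binary.values[0, 0])

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(_consensus([[0.5]]), float("nan"))


class TestChangeMap:
    def test_identity_maps_to_stable_or_absent(self):
        b = _binary([[1.0, 0.0], [0.0, 1.0]])
        cm = change_map(b, b)
        assert np.all(np.isin(cm.values, [STABLE, ABSENT]))
        assert not np.any(cm.values == GAINED) and not np.any(cm.values == LOST)

    def test_scenario_all_zero_loses_footprint(self):
        p = _binary([[1.0, 0.0], [1.0, 1.0]])
        s = _binary(np.zeros((2, 2)))
        cm = change_map(p, s)
        assert (cm.values == LOST).sum() == 3
        assert (cm.values == ABSENT).sum() == 1

    def test_categories_partition_valid_cells(self):
        rng = np.random.default_rng(1)
        p = _binary(rng.integers(0, 2, size=(6, 6)).astype(float))
        s = _binary(rng.integers(0, 2, size=(6, 6)).astype(float))
        cm = change_map(p, s)
        counts = sum(int((cm.values == c).sum()) for c in (ABSENT, STABLE, LOST, GAINED))
        assert counts == 36

    def test_grid_mismatch_rejected(self):
        with pytest.raises(Exception):
            change_map(_binary([[1.0]]), _binary([[1.0]], west=10.0))


class TestCellArea:
    def test_equatorial_half_degree_cell(self):
        grid = RasterGrid(2, 2, west=0.0, south=-0.5, east=1.0, north=0.5)
        # row 0 spans 0..0.5 deg latitude
        oracle = spherical_cell_area_quad(0.0, 0.5, 0.0, 0.5, EARTH_RADIUS_KM)
        assert cell_area_km2(0, grid) == pytest.approx(oracle, rel=1e-9)
        assert cell_area_km2(0, grid) == pytest.approx(3091.0, rel=2e-3)

    def test_polar_half_degree_cell(self):
        grid = RasterGrid(2, 2, west=0.0, south=89.0, east=1.0, north=90.0)
        oracle = spherical_cell_area_quad(0.0, 0.5, 89.5, 90.0, EARTH_RADIUS_KM)
        assert cell_area_km2(0, grid) == pytest.approx(oracle, rel=1e-9)
        assert cell_area_km2(0, grid) == pytest.approx(13.5, rel=0.02)

    def test_matches_numerical_integration_at_many_latitudes(self):
        grid = RasterGrid(36, 8, west=-10.0, south=-90.0, east=-6.0, north=-72.0)
        for row in range(36):
            north = grid.north - row * grid.cell_height
            oracle = spherical_cell_area_quad(0.0, grid.cell_width,
                                              north - grid.cell_height, north,
                                              EARTH_RADIUS_KM)
            assert cell_area_km2(row, grid) == pytest.approx(oracle, rel=1e-6)

    def test_global_grid_sums_to_sphere_area(self):
        grid = RasterGrid(180, 360, west=-180.0, south=-90.0, east=180.0, north=90.0)
        rows = np.arange(180)
        total = (cell_area_km2(rows, grid) * 360).sum()
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_KM**2, rel=1e-6)

    def test_row_out_of_grid_rejected(self):
        grid = RasterGrid(2, 2, west=0.0, south=0.0, east=1.0, north=1.0)
        with pytest.raises(ValueError):
            cell_area_km2(5, grid)


class TestAreasAndChange:
    def test_empty_range_zero_area(self):
        assert total_area_km2(_binary(np.zeros((3, 3)))) == 0.0

    def test_single_equatorial_cell(self):
        grid = RasterGrid(1, 1, west=0.0, south=-0.25, east=0.5, north=0.25)
        vals = np.array([[1.0]])
        b = BinaryRangeRaster(grid=grid, values=vals, threshold_used=0.5)
        assert total_area_km2(b) == pytest.approx(3091.0, rel=2e-3)

    def test_area_additive_over_disjoint_sets(self):
        rng = np.random.default_rng(2)
        a = (rng.uniform(size=(5, 5)) < 0.4).astype(float)
        b_vals = np.where(a == 1.0, 0.0, (rng.uniform(size=(5, 5)) < 0.5).astype(float))
        both = np.clip(a + b_vals, 0, 1)
        assert (total_area_km2(_binary(a)) + total_area_km2(_binary(b_vals))
                == pytest.approx(total_area_km2(_binary(both)), rel=1e-12))

    @pytest.mark.parametrize("present,scenario,expected", [
        (100.0, 110.0, 10.0), (100.0, 100.0, 0.0), (200.0, 150.0, -25.0)])
    def test_percent_change(self, present, scenario, expected):
        assert percent_change(present, scenario) == pytest.approx(expected)

    def test_percent_change_zero_present_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)

    def test_summary_identities(self):
        rng = np.random.default_rng(3)
        p = _binary(rng.integers(0, 2, size=(8, 8)).astype(float), south=-30.0)
        s = _binary(rng.integers(0, 2, size=(8, 8)).astype(float), south=-30.0)
        cs = summarize_change("sp", p, s, "future")
        assert cs.stable_km2 + cs.lost_km2 == pytest.approx(cs.present_area_km2, abs=1e-9)
        assert cs.stable_km2 + cs.gained_km2 == pytest.approx(cs.scenario_area_km2, abs=1e-9)
        assert 0.0 <= cs.percent_maintained <= 100.0

    def test_identical_scenario_exact_identity(self):
        p = _binary([[1.0, 0.0], [1.0, 1.0]])
        cs = summarize_change("sp", p, p, "same")
        assert cs.percent_change == 0.0
        assert cs.percent_maintained == 100.0
        assert cs.gained_km2 == cs.lost_km2 == 0.0

    def test_maintained_100_iff_footprint_subset(self):
        p = _binary([[1.0, 0.0]])
        superset = _binary([[1.0, 1.0]])
        assert summarize_change("sp", p, superset, "x").percent_maintained == 100.0
        disjoint = _binary([[0.0, 1.0]])
        assert summarize_change("sp", p, disjoint, "x").percent_maintained == 0.0
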