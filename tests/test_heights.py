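"""Percentile ladders, zonal pixel extraction and the ultrasonic equations."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from canopy3d.heights import (
    empirical_percentile,
    percentile_grid,
    percentile_height,
    percentile_ladder,
    plot_pixel_values,
    ultrasonic_distance,
    ultrasonic_height,
    UltrasonicReading,
)
from canopy3d.raster import Raster


def ladder_oracle(values, percentile):
    """Sort-based linear order-statistic interpolation, written independently."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return v[0]
    rank = percentile / 100.0 * (n - 1)
    lo = int(np.floor(rank))
    if lo >= n - 1:
        return v[-1]
    frac = rank - lo
    return v[lo] + (v[lo + 1] - v[lo]) * frac


class TestLadder:
    def test_cardinality(self):
        values = np.arange(10.0)
        assert len(percentile_ladder(values, step=0.5)) == 200
        assert len(percentile_ladder(values, step=1.0)) == 100
        grid = percentile_grid(0.5)
        assert grid[0] == 0.5 and grid[-1] == 100.0

    def test_constant_values(self):
        lad = percentile_ladder(np.full(37, 0.42), step=0.5)
        np.testing.assert_array_equal(lad.heights, np.full(200, 0.42))

    def test_two_point_endpoint_and_quartiles(self):
        lad = percentile_ladder([0.0, 1.0], step=25.0)
        assert lad.height_at(100.0) == 1.0
        for p, h in zip(lad.percentiles, lad.heights):
            assert h == pytest.approx(ladder_oracle([0.0, 1.0], p), abs=1e-15)

    def test_against_sort_based_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            values = rng.normal(0, 1, size=rng.integers(1, 60))
            p = float(rng.uniform(0, 100))
            assert percentile_height(values, p) == pytest.approx(
                ladder_oracle(values, p), abs=1e-12
            )

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=50),
        st.sampled_from([0.5, 1.0, 5.0, 25.0]),
    )
    def test_heights_monotone_in_percentile(self, values, step):
        lad = percentile_ladder(values, step=step)
        assert np.all(np.diff(lad.heights) >= -1e-12)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            percentile_ladder([], step=0.5)

    def test_empirical_percentile_round_trip(self):
        rng = np.random.default_rng(31)
        values = rng.normal(1.0, 0.2, size=500)
        target = float(np.quantile(values, 0.87))
        p = empirical_percentile(values, target)
        assert percentile_height(values, p) == pytest.approx(target, abs=1e-9)


def block_raster(n=20, value=0.0):
    return Raster(np.full((n, n), value), origin=(0.0, n * 0.1), cell_size=0.1)


class TestPlotPixels:
    def test_uniform_block(self):
        raster = block_raster(value=0.8)
        # polygon covering exactly a 10x10 block of cells
        poly = shapely.box(0.0, 0.0, 1.0, 1.0)
        values = plot_pixel_values(raster, poly)
        assert values.shape == (100,)
        assert np.all(values == 0.8)

    def test_polygon_outside_raster(self):
        raster = block_raster()
        with pytest.raises(ValueError):
            plot_pixel_values(raster, shapely.box(10, 10, 11, 11))

    def test_matches_cell_center_scan_oracle(self):
        rng = np.random.default_rng(9)
        raster = Raster(rng.normal(size=(15, 18)), origin=(-0.3, 1.2), cell_size=0.07)
        poly = shapely.Polygon([(0.0, 0.0), (0.9, 0.1), (0.7, 0.9), (0.05, 0.6)])
        xs, ys = raster.cell_centers()
        expected = []
        for i, yc in enumerate(ys):
            for j, xc in enumerate(xs):
                p = shapely.Point(xc, yc)
                inside = poly.contains(p)
                if not inside and poly.covers(p):
                    minx, miny, *_ = poly.bounds
                    inside = abs(xc - minx) < 1e-9 or abs(yc - miny) < 1e-9
                if inside:
                    expected.append(raster.values[i, j])
        got = plot_pixel_values(raster, poly)
        assert sorted(got) == pytest.approx(sorted(expected))

    def test_nodata_cells_are_excluded(self):
        raster = block_raster(value=1.0)
        raster.values[15, 5] = raster.nodata  # row 15 -> y 0.45, inside the box
        values = plot_pixel_values(raster, shapely.box(0.0, 0.0, 1.0, 1.0))
        assert values.shape == (99,)


class TestUltrasonic:
    @pytest.mark.parametrize("volts,expected", [(0.0, 11.641), (1.0, 40.757), (2.0, 69.873)])
    def test_calibration_line(self, volts, expected):
        assert ultrasonic_distance(volts) == pytest.approx(expected, abs=1e-12)

    def test_voltage_range_enforced(self):
        with pytest.raises(ValueError):
            ultrasonic_distance(-0.1)
        with pytest.raises(ValueError):
            ultrasonic_distance(10.5)

    def test_height_equation(self):
        assert ultrasonic_height(1.0, 0.3, unit_scale=1.0) == pytest.approx(0.7)
        assert ultrasonic_height(2.0, 2.0, unit_scale=1.0) == 0.0

    def test_negative_heights_are_flagged_not_rejected(self):
        reading = UltrasonicReading(voltage=8.0, sensor_height=2.0)
        # 8 V -> 244.6 cm -> 2.446 m > sensor height
        assert reading.canopy_height < 0
        assert reading.negative

    def test_unit_scale_default_is_centimeters(self):
        reading = UltrasonicReading(voltage=4.0, sensor_height=2.0)
        assert reading.distance == pytest.approx(128.105)
        assert reading.canopy_height == pytest.approx(2.0 - 1.28105)
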