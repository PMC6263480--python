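"""Soil sampling, DTM interpolation and height-map construction."""

import numpy as np
import pytest

from canopy3d.raster import CongruenceError, Raster
from canopy3d.surface import (
    SoilSample,
    fit_variogram,
    height_map,
    interpolate_dtm,
    sample_soil_pixels,
)


def grid(n=30, cell=0.1, values=None):
    vals = np.zeros((n, n)) if values is None else values
    return Raster(vals, origin=(0.0, n * cell), cell_size=cell)


def plane_raster(n=40, cell=0.1, a=0.02, b=-0.015, c=1.0):
    xs = (np.arange(n) + 0.5) * cell
    ys = n * cell - (np.arange(n) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    return Raster(a * gx + b * gy + c, origin=(0.0, n * cell), cell_size=cell)


class TestSoilSampling:
    def test_sample_size_is_rounded_fraction(self):
        n = 10
        dsm = grid(n)
        mask = grid(n, values=np.ones((n, n)))
        sample = sample_soil_pixels(dsm, mask, fraction=0.4, seed=0)
        assert len(sample) == 40

    def test_full_fraction_takes_every_soil_cell(self):
        dsm = grid(8)
        mask_vals = np.zeros((8, 8))
        mask_vals[::2, :] = 1.0
        sample = sample_soil_pixels(dsm, grid(8, values=mask_vals), fraction=1.0, seed=1)
        assert len(sample) == 32

    def test_deterministic_under_seed(self):
        dsm = grid(12)
        mask = grid(12, values=np.ones((12, 12)))
        s1 = sample_soil_pixels(dsm, mask, 0.3, seed=9)
        s2 = sample_soil_pixels(dsm, mask, 0.3, seed=9)
        np.testing.assert_array_equal(s1.rows, s2.rows)
        np.testing.assert_array_equal(s1.cols, s2.cols)

    def test_empty_soil_mask_rejected(self):
        dsm = grid(5)
        with pytest.raises(ValueError):
            sample_soil_pixels(dsm, grid(5), fraction=0.4, seed=0)


class TestDtmInterpolation:
    @pytest.mark.parametrize("method", ["kriging", "idw"])
    def test_constant_field(self, method):
        dsm = grid(15, values=np.full((15, 15), 3.25))
        mask = grid(15, values=np.ones((15, 15)))
        sample = sample_soil_pixels(dsm, mask, 0.5, seed=2)
        dtm = interpolate_dtm(sample, dsm, method=method)
        np.testing.assert_allclose(dtm.values, 3.25, atol=1e-12)

    @pytest.mark.parametrize("method", ["kriging", "idw"])
    def test_exact_at_sampled_cells(self, method):
        rng = np.random.default_rng(6)
        dsm = plane_raster()
        dsm.values += rng.normal(0, 0.05, dsm.shape)  # rough surface
        mask = grid(40, values=np.ones((40, 40)))
        sample = sample_soil_pixels(dsm, mask, 0.3, seed=3)
        dtm = interpolate_dtm(sample, dsm, method=method)
        err = np.abs(dtm.values[sample.rows, sample.cols] - sample.values)
        assert err.max() < 1e-6

    def test_planar_recovery(self):
        dsm = plane_raster()
        mask = grid(40, values=np.ones((40, 40)))
        sample = sample_soil_pixels(dsm, mask, 0.4, seed=4)
        dtm = interpolate_dtm(sample, dsm, method="kriging")
        assert np.abs(dtm.values - dsm.values).max() < 0.01

    def test_sloped_terrain_error_quantile(self):
        # 40 % soil sampling on a noise-free sloped surface: 95th percentile
        # of |error| stays within 0.02 m at default grids
        dsm = plane_raster(n=60, a=0.01, b=0.008)
        mask_vals = (np.random.default_rng(5).random((60, 60)) < 0.5).astype(float)
        mask = grid(60, values=mask_vals)
        sample = sample_soil_pixels(dsm, mask, 0.4, seed=5)
        dtm = interpolate_dtm(sample, dsm, method="kriging")
        assert np.percentile(np.abs(dtm.values - dsm.values), 95) <= 0.02

    def test_too_few_or_collinear_samples_rejected(self):
        dsm = grid(10)
        few = SoilSample(
            rows=np.array([0, 1]), cols=np.array([0, 1]),
            x=np.array([0.05, 0.15]), y=np.array([0.95, 0.85]),
            values=np.array([0.0, 0.1]), fraction=0.1,
        )
        with pytest.raises(ValueError):
            interpolate_dtm(few, dsm)
        collinear = SoilSample(
            rows=np.zeros(5, int), cols=np.arange(5),
            x=(np.arange(5) + 0.5) * 0.1, y=np.full(5, 0.95),
            values=np.linspace(0, 1, 5), fraction=0.1,
        )
        with pytest.raises(ValueError):
            interpolate_dtm(collinear, dsm, method="kriging")

    def test_variogram_fit_is_well_posed(self):
        dsm = plane_raster()
        mask = grid(40, values=np.ones((40, 40)))
        sample = sample_soil_pixels(dsm, mask, 0.2, seed=8)
        vg = fit_variogram(sample)
        assert vg.nugget >= 1e-6 and vg.sill > 0 and vg.range_ > 0
        assert vg(np.array([0.0]))[0] == 0.0  # exact interpolation hinges on this


class TestHeightMap:
    def test_identical_surfaces_difference_is_zero(self):
        dsm = plane_raster()
        out = height_map(dsm, dsm.like(dsm.values.copy(), role="dtm"))
        np.testing.assert_array_equal(out.values, np.zeros(dsm.shape))

    def test_flat_dtm_recovers_plot_height(self):
        dsm = grid(10)
        dsm.values[2:5, 2:5] = 0.73
        out = height_map(dsm, dsm.like(np.zeros((10, 10)), role="dtm"))
        assert np.all(out.values[2:5, 2:5] == 0.73)
        assert out.role == "height_map"

    def test_nodata_propagates_and_negatives_survive(self):
        dsm = grid(6, values=np.full((6, 6), 0.5))
        dtm_vals = np.full((6, 6), 0.6)
        dsm.values[0, 0] = dsm.nodata
        out = height_map(dsm, dsm.like(dtm_vals, role="dtm"))
        assert out.values[0, 0] == out.nodata
        assert out.values[1, 1] == pytest.approx(-0.1)

    def test_congruence_enforced(self):
        dsm = grid(6)
        other = Raster(np.zeros((6, 6)), origin=(1.0, 0.6), cell_size=0.1)
        with pytest.raises(CongruenceError):
            height_map(dsm, other)
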