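"""Tilt estimation, counter-rotation and ground-baseline removal."""

import numpy as np
import pytest

from canopy3d.cloud import PointCloud
from canopy3d.correction import (
    DegenerateFitError,
    correct_ground_baseline,
    correct_tilt,
    fit_projection_slope,
    rotate_cloud,
    slope_to_angle,
)
from canopy3d.geometry import trim_cloud
from canopy3d.scene import ScanPose, simulate_lidar_scan


def ols_oracle(a, o):
    """Closed-form normal equations, independent of the fit implementation."""
    n = len(a)
    sa, so, saa, sao = a.sum(), o.sum(), (a * a).sum(), (a * o).sum()
    slope = (n * sao - sa * so) / (n * saa - sa * sa)
    return slope, (so - slope * sa) / n


class TestProjectionFit:
    def test_exact_line(self):
        y = np.linspace(-1, 1, 40)
        pts = np.column_stack([np.zeros(40), y, 0.2 * y + 1.0])
        slope, intercept = fit_projection_slope(pts, "yz")
        assert slope == pytest.approx(0.2, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)

    def test_horizontal_cloud_has_zero_slope(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.zeros(20), np.full(20, 0.5)])
        assert fit_projection_slope(pts, "xz")[0] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("projection", ["yz", "xz", "xy"])
    def test_against_normal_equations_oracle(self, projection):
        rng = np.random.default_rng(17)
        for _ in range(20):
            pts = rng.normal(0, 2, size=(300, 3))
            ia, io = {"yz": (1, 2), "xz": (0, 2), "xy": (0, 1)}[projection]
            want = ols_oracle(pts[:, ia], pts[:, io])
            got = fit_projection_slope(pts, projection)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_degenerate_abscissa_raises(self):
        pts = np.column_stack([np.zeros(5), np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateFitError):
            fit_projection_slope(pts, "xz")


class TestSlopeAngleRotation:
    @pytest.mark.parametrize(
        "slope,deg", [(1.0, 45.0), (0.0, 0.0), (0.1, 5.7105931375)]
    )
    def test_slope_to_angle(self, slope, deg):
        assert slope_to_angle(slope) == pytest.approx(deg, abs=1e-9)

    def test_rotation_example_about_x(self):
        cloud = PointCloud([[0.0, 1.0, 1.0]])
        out = rotate_cloud(cloud, "x", -45.0)
        np.testing.assert_allclose(out.points, [[0.0, np.sqrt(2), 0.0]], atol=1e-12)

    def test_zero_angle_is_identity_and_inverse_restores(self):
        rng = np.random.default_rng(2)
        cloud = PointCloud(rng.normal(size=(100, 3)))
        np.testing.assert_array_equal(rotate_cloud(cloud, "y", 0.0).points, cloud.points)
        roundtrip = rotate_cloud(rotate_cloud(cloud, "z", 33.0), "z", -33.0)
        np.testing.assert_allclose(roundtrip.points, cloud.points, atol=1e-12)


class TestCorrectTilt:
    def test_untilted_scene_reports_no_tilt(self, flat_scene, level_pose):
        cloud, _ = simulate_lidar_scan(flat_scene, 4, level_pose, noise_sd=0.0, seed=1)
        _, est = correct_tilt(cloud)
        assert est.converged and est.iterations == 1
        assert all(abs(a) < 0.01 for a in est.angles())

    def test_known_tilt_round_trip(self, flat_scene):
        pose = ScanPose(roll=2.0, pitch=-3.0, yaw=1.0, sensor_height=2.0)
        cloud, _ = simulate_lidar_scan(flat_scene, 4, pose, seed=5)
        _, est = correct_tilt(cloud)
        roll, pitch, yaw = est.angles()
        assert roll == pytest.approx(2.0, abs=0.1)
        assert pitch == pytest.approx(-3.0, abs=0.1)
        assert yaw == pytest.approx(1.0, abs=0.1)

    def test_residual_slopes_below_tolerance(self, flat_scene):
        pose = ScanPose(roll=4.0, pitch=2.0, yaw=-2.0, sensor_height=2.0)
        cloud, _ = simulate_lidar_scan(flat_scene, 4, pose, seed=6)
        _, est = correct_tilt(cloud, tolerance=1e-6)
        assert all(abs(s) < 1e-6 for s in est.residual_slopes)

    def test_idempotent_at_tolerance(self, flat_scene):
        pose = ScanPose(roll=3.0, pitch=1.0, yaw=0.5, sensor_height=2.0)
        cloud, _ = simulate_lidar_scan(flat_scene, 4, pose, seed=8)
        corrected, _ = correct_tilt(trim_cloud(cloud, 1.524))
        again, _ = correct_tilt(PointCloud(corrected.points, "trimmed"))
        assert np.max(np.abs(again.points - corrected.points)) < 1e-6

    def test_preserves_pairwise_distances(self, flat_scene):
        pose = ScanPose(roll=5.0, pitch=-4.0, yaw=2.0, sensor_height=2.0)
        cloud, _ = simulate_lidar_scan(
            flat_scene, 4, pose, density={"side": 100, "middle": 120}, seed=9
        )
        corrected, _ = correct_tilt(cloud)
        before = np.linalg.norm(
            cloud.points[:, None, :] - cloud.points[None, :, :], axis=-1
        )
        after = np.linalg.norm(
            corrected.points[:, None, :] - corrected.points[None, :, :], axis=-1
        )
        assert np.max(np.abs(before - after)) < 1e-9


class TestGroundBaseline:
    def test_histogram_peak_finds_flat_ground(self, noise_free_scan):
        cloud, _ = noise_free_scan
        trimmed = trim_cloud(cloud, 1.524)
        above, base = correct_ground_baseline(trimmed, strategy="histogram_peak")
        assert base.ground_z == pytest.approx(-2.0, abs=0.01)
        # ground returns cluster at zero after the shift
        assert np.percentile(above.z, 1) == pytest.approx(0.0, abs=0.02)

    def test_sensor_height_strategy_shifts_exactly(self, noise_free_scan):
        cloud, _ = noise_free_scan
        trimmed = trim_cloud(cloud, 1.524)
        above, base = correct_ground_baseline(
            trimmed, strategy="sensor_height", sensor_height=2.0
        )
        assert base.ground_z == -2.0
        np.testing.assert_allclose(above.z, trimmed.z + 2.0, atol=1e-12)

    def test_histogram_falls_back_when_no_ground_support(self):
        # a canopy-only sliver: nearly all mass above the median band
        rng = np.random.default_rng(4)
        z = np.concatenate([rng.normal(-1.3, 0.01, 60), [-2.0]])
        pts = np.column_stack([rng.uniform(-1, 1, 61), rng.uniform(-1, 1, 61), z])
        cloud = PointCloud(pts, "trimmed")
        with pytest.warns(RuntimeWarning):
            _, base = correct_ground_baseline(
                cloud, strategy="histogram_peak", sensor_height=2.0, min_lower_points=50
            )
        assert base.fallback and base.strategy == "sensor_height"
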