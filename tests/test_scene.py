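"""The synthetic scene generator: determinism, ground truth, sensor models."""

import dataclasses

import numpy as np
import pytest

from canopy3d.correction import fit_projection_slope
from canopy3d.heights import percentile_height
from canopy3d.scene import (
    CanopyConfig,
    ConfigError,
    SceneConfig,
    ScanPose,
    TerrainConfig,
    generate_field_scene,
    generate_reference_heights,
    simulate_dsm,
    simulate_lidar_scan,
    simulate_ultrasonic,
)


def flat_cfg(**kwargs):
    base = dict(
        n_plots=10,
        plots_per_row=10,
        terrain=TerrainConfig(0.0, 0.0, 0.0),
        height_range=(0.7, 0.7),
    )
    base.update(kwargs)
    return SceneConfig(**base)


class TestSceneGeneration:
    def test_identical_seed_identical_scene(self):
        cfg = SceneConfig(n_plots=100)
        a = generate_field_scene(cfg, seed=7)
        b = generate_field_scene(SceneConfig(n_plots=100), seed=7)
        np.testing.assert_array_equal(a.true_height, b.true_height)
        assert a.terrain_elevation(1.3, 2.2) == b.terrain_elevation(1.3, 2.2)

    def test_heights_stay_in_configured_range(self):
        scene = generate_field_scene(SceneConfig(n_plots=100, height_range=(0.2, 1.0)), seed=3)
        assert scene.true_height.shape == (100,)
        assert np.all((scene.true_height >= 0.2) & (scene.true_height <= 1.0))

    def test_degenerate_terrain_is_exactly_flat(self):
        scene = generate_field_scene(flat_cfg(), seed=1)
        xs = np.linspace(-5, 20, 50)
        np.testing.assert_array_equal(scene.terrain_elevation(xs, xs * 0.5), np.zeros(50))

    def test_invalid_config_names_the_field(self):
        with pytest.raises(ConfigError, match="cover_fraction"):
            generate_field_scene(
                SceneConfig(canopy=CanopyConfig(cover_fraction=1.4)), seed=0
            )


class TestLidarScan:
    def test_point_budget_matches_positions(self, flat_scene, level_pose):
        _, records = simulate_lidar_scan(flat_scene, 4, level_pose, seed=2)
        by_pos = {r.position: r.n_points for r in records}
        assert abs(by_pos["middle"] - 8000) / 8000 < 0.05
        assert abs(by_pos["side"] - 6000) / 6000 < 0.05

    def test_untilted_scan_has_flat_projections(self, flat_scene, level_pose):
        cloud, _, details = simulate_lidar_scan(
            flat_scene, 4, level_pose, noise_sd=0.0, seed=3, return_details=True
        )
        ground = np.vstack([cloud.points[np.concatenate([d["is_ground"] for d in details])]])
        for projection in ("yz", "xz", "xy"):
            # xy slope of a symmetric rectangle and both z-slopes of a flat
            # floor vanish when no pose is applied
            slope, _ = fit_projection_slope(ground, projection)
            assert abs(slope) < 1e-6

    def test_percentile_self_consistency(self, flat_scene, level_pose):
        _, records, details = simulate_lidar_scan(
            flat_scene, 4, level_pose, noise_sd=0.0, seed=4, return_details=True
        )
        for rec, det in zip(records, details):
            got = percentile_height(det["above_ground"], rec.empirical_true_percentile)
            assert got == pytest.approx(rec.true_height, abs=1e-9)

    def test_scan_is_deterministic(self, flat_scene, level_pose):
        a, _ = simulate_lidar_scan(flat_scene, 4, level_pose, seed=11)
        b, _ = simulate_lidar_scan(flat_scene, 4, level_pose, seed=11)
        np.testing.assert_array_equal(a.points, b.points)

    def test_scan_needs_interior_middle_plot(self, flat_scene, level_pose):
        with pytest.raises(ValueError):
            simulate_lidar_scan(flat_scene, 0, level_pose, seed=0)

    def test_starved_density_rejected(self, flat_scene, level_pose):
        from canopy3d.scene import GenerationError

        with pytest.raises(GenerationError):
            simulate_lidar_scan(
                flat_scene, 4, level_pose, density={"side": 5, "middle": 20}, seed=0
            )


class TestUltrasonic:
    def test_top_of_canopy_echo_recovers_height(self):
        # dense flat sward at exactly h: echo at the 100th percentile, no noise
        cfg = flat_cfg(canopy=CanopyConfig(cover_fraction=1.0, height_sd_fraction=0.0))
        scene = generate_field_scene(cfg, seed=5)
        pose = ScanPose(sensor_height=2.0)
        v = simulate_ultrasonic(
            scene, 4, pose, echo_depth_percentile=100.0, noise_sd=0.0, seed=6
        )
        from canopy3d.heights import ultrasonic_distance, ultrasonic_height

        h_c = ultrasonic_height(2.0, ultrasonic_distance(v))
        assert h_c == pytest.approx(0.7, abs=1e-6)

    def test_empty_footprint_echoes_from_ground(self):
        cfg = flat_cfg(canopy=CanopyConfig(cover_fraction=0.0, height_sd_fraction=0.08))
        scene = generate_field_scene(cfg, seed=7)
        v = simulate_ultrasonic(scene, 4, ScanPose(sensor_height=2.0), noise_sd=0.0, seed=8)
        from canopy3d.heights import ultrasonic_distance, ultrasonic_height

        assert ultrasonic_height(2.0, ultrasonic_distance(v)) == pytest.approx(0.0, abs=1e-9)

    def test_slanted_cart_over_bare_ground_reads_negative(self):
        cfg = flat_cfg(canopy=CanopyConfig(cover_fraction=0.0))
        scene = generate_field_scene(cfg, seed=9)
        pose = ScanPose(roll=8.0, pitch=6.0, sensor_height=2.0)
        v = simulate_ultrasonic(scene, 4, pose, noise_sd=0.0, seed=10)
        from canopy3d.heights import ultrasonic_distance, ultrasonic_height

        assert ultrasonic_height(2.0, ultrasonic_distance(v)) < 0


class TestDsm:
    def test_bare_flat_field_is_all_zero_soil(self):
        cfg = flat_cfg(canopy=CanopyConfig(cover_fraction=0.0))
        scene = generate_field_scene(cfg, seed=12)
        dsm, mask = simulate_dsm(scene, gsd=0.2, noise_sd=0.0, canopy_error_sd=0.0, seed=13)
        np.testing.assert_array_equal(dsm.values, np.zeros(dsm.shape))
        assert np.all(mask.values == 1.0)

    def test_full_cover_at_exact_height(self):
        cfg = flat_cfg(canopy=CanopyConfig(cover_fraction=1.0, height_sd_fraction=0.0))
        scene = generate_field_scene(cfg, seed=14)
        dsm, mask = simulate_dsm(scene, gsd=0.2, noise_sd=0.0, canopy_error_sd=0.0, seed=15)
        canopy = mask.values == 0.0
        assert canopy.any()
        np.testing.assert_allclose(dsm.values[canopy], 0.7, atol=1e-12)

    def test_bit_identical_under_seed(self):
        scene = generate_field_scene(SceneConfig(n_plots=10, plots_per_row=10), seed=16)
        a, am = simulate_dsm(scene, gsd=0.15, seed=17)
        b, bm = simulate_dsm(scene, gsd=0.15, seed=17)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(am.values, bm.values)

    def test_unresolvable_gsd_rejected(self):
        scene = generate_field_scene(flat_cfg(), seed=18)
        with pytest.raises(ConfigError):
            simulate_dsm(scene, gsd=2.0, seed=19)


class TestReferenceHeights:
    def test_noise_free_reference_equals_truth(self, default_scene):
        table = generate_reference_heights(default_scene, 1, "A", noise_sd=0.0, seed=20)
        np.testing.assert_array_equal(table.height_m.to_numpy(), default_scene.true_height)
        assert set(table.method) == {"A"}

    def test_replicate_averaging_is_unbiased(self):
        # CLT bound: with 10000 plots and 3 replicates of sd 0.02, the mean
        # reference-minus-truth error stays within 3 sigma of zero
        scene = generate_field_scene(
            SceneConfig(n_plots=10000, plots_per_row=100), seed=21
        )
        table = generate_reference_heights(scene, 1, "A", noise_sd=0.02, seed=22)
        err = table.height_m.to_numpy() - scene.true_height
        assert abs(err.mean()) < 3 * 0.02 / np.sqrt(3 * 10000)
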