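"""Shared fixtures: small deterministic scenes and scan products."""

import numpy as np
import pytest

from canopy3d.scene import (
    CanopyConfig,
    SceneConfig,
    TerrainConfig,
    ScanPose,
    generate_field_scene,
    simulate_lidar_scan,
)

PLOT_WIDTH = 1.524


@pytest.fixture
def flat_scene():
    """Flat, smooth terrain with a uniform 0.7 m sward: exact-recovery scenes."""
    cfg = SceneConfig(
        n_plots=10,
        plots_per_row=10,
        terrain=TerrainConfig(slope_x=0.0, slope_y=0.0, roughness_sd=0.0),
        height_range=(0.7, 0.7),
    )
    return generate_field_scene(cfg, seed=11)


@pytest.fixture
def default_scene():
    """Study-like scene: sloped rough terrain, varied plot heights."""
    cfg = SceneConfig(n_plots=10, plots_per_row=10)
    return generate_field_scene(cfg, seed=7)


@pytest.fixture
def level_pose():
    return ScanPose(sensor_height=2.0)


@pytest.fixture
def noise_free_scan(flat_scene, level_pose):
    """Untilted noise-free scan of plots 3-5 with its ground-truth records."""
    cloud, records = simulate_lidar_scan(
        flat_scene, 4, level_pose, noise_sd=0.0, seed=21
    )
    return cloud, records


def random_cloud(rng, n=200, scale=2.0):
    from canopy3d.cloud import PointCloud

    return PointCloud(rng.normal(0, scale, size=(n, 3)), frame_state="raw")
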