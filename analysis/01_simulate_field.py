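#!/usr/bin/env python
"""Generate one synthetic wheat field and export example sensor artifacts.

Builds the default 100-plot scene, simulates one static three-plot LiDAR
scan, one DSM with its soil mask, and a reference-height table, then writes
small summary tables under results/ (bulky rasters and clouds go to
scratch/, which is disposable).
"""

from pathlib import Path

import numpy as np

from canopy3d import io as c3dio
from canopy3d.raster import write_ascii_grid
from canopy3d.scene import (
    SceneConfig,
    ScanPose,
    build_plot_polygons,
    generate_field_scene,
    generate_reference_heights,
    scene_summary,
    simulate_dsm,
    simulate_lidar_scan,
)

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    scene = generate_field_scene(SceneConfig(height_range=(0.6, 1.0)), seed=SEED)
    print(f"field: {scene.n_plots} plots, heights "
          f"{scene.true_height.min():.2f}-{scene.true_height.max():.2f} m")

    pose = ScanPose(roll=2.5, pitch=-1.8, yaw=0.7, sensor_height=2.0)
    cloud, records = simulate_lidar_scan(scene, 4, pose, seed=SEED + 1)
    c3dio.write_ply(cloud, SCRATCH / "scan_plots_3_4_5.ply")
    for rec in records:
        print(f"  plot {rec.plot_id} ({rec.position}): {rec.n_points} points, "
              f"true height {rec.true_height:.3f} m at the "
              f"{rec.empirical_true_percentile:.1f}th percentile")

    dsm, mask = simulate_dsm(scene, gsd=0.1, seed=SEED + 2)
    write_ascii_grid(dsm, SCRATCH / "dsm.asc")
    write_ascii_grid(mask, SCRATCH / "soil_mask.asc")
    c3dio.write_geojson(build_plot_polygons(scene), SCRATCH / "plots.geojson")
    soil_pct = 100 * float(mask.values.mean())
    print(f"DSM {dsm.shape[0]}x{dsm.shape[1]} cells at {dsm.cell_size} m GSD, "
          f"{soil_pct:.0f}% soil")

    refs = generate_reference_heights(scene, campaign=1, method="A", seed=SEED + 3)
    refs.to_csv(RESULTS / "reference_heights_campaign1.csv", index=False)
    c3dio.write_json(scene_summary(scene), RESULTS / "scene_summary.json")
    print(f"reference table and scene summary written to {RESULTS}")


if __name__ == "__main__":
    main()
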