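"""End-to-end orchestration of the synthetic sensor-comparison study.

``run_simulation_study`` simulates a season — five data-collection
campaigns over one field of plots whose heights grow between campaigns —
and pushes each campaign through the three sensing pipelines:

* LiDAR: static three-plot scans with a random cart pose; trim, tilt
  correction, ground baseline, split, 0.5 % percentile ladders (a raw
  route skips tilt correction for the processed-versus-raw comparison);
* ultrasonic: one echo per plot, decoded through the voltage calibration;
* UAS: a DSM per campaign, soil-pixel sampling, kriged DTM, height map,
  and 1 % pixel-percentile ladders per plot delineation.

The evaluation layer then reproduces the study's derived tables: per-
campaign minimum RMSE for raw and processed clouds with percent reductions,
method-category and plot-position breakdowns, and the pooled per-sensor
comparison at the per-category optimal percentiles. Every random draw flows
from the master seed, so a result bundle is a pure function of
``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import io as c3dio
from .cloud import PointCloud
from .correction import correct_ground_baseline, correct_tilt
from .evaluation import (
    CAMPAIGN_METHODS,
    average_rmse_increase,
    evaluate,
    optimal_percentile,
    optimal_r2_percentile,
    percent_exceed,
    percent_reduction,
)
from .geometry import split_cloud, trim_cloud
from .heights import (
    DEFAULT_UNIT_SCALE,
    LIDAR_STEP,
    UAS_STEP,
    PercentileLadder,
    percentile_ladder,
    plot_pixel_values,
    ultrasonic_distance,
    ultrasonic_height,
)
from .scene import (
    FieldScene,
    ScanPose,
    SceneConfig,
    build_plot_polygons,
    generate_field_scene,
    generate_reference_heights,
    simulate_dsm,
    simulate_lidar_scan,
    simulate_ultrasonic,
)
from .surface import height_map, interpolate_dtm, sample_soil_pixels

logger = logging.getLogger("canopy3d")


@dataclass
class StudyConfig:
    """Configuration of the synthetic five-campaign study.

    Growth factors scale each plot's mature height per campaign, so the same
    plot is re-measured as it grows. Pose angles are drawn per scan from
    centered normals (degrees) and clipped to +-10 deg — the few-degree
    slants a pushed cart shows on rough ground.
    """

    scene: SceneConfig = field(default_factory=lambda: SceneConfig(height_range=(0.6, 1.0)))
    campaigns: tuple[int, ...] = (1, 2, 3, 4, 5)
    growth_factors: tuple[float, ...] = (0.35, 0.55, 0.8, 0.95, 1.0)
    sensor_height: float = 2.0
    pose_sd_deg: tuple[float, float, float] = (3.0, 3.0, 2.0)  # roll, pitch, yaw
    lidar_density: dict = field(default_factory=lambda: {"side": 6000, "middle": 8000})
    lidar_noise_sd: float = 0.003
    ground_fraction: float = 0.3
    baseline_strategy: str = "histogram_peak"
    echo_depth_percentile: float = 25.0
    ultrasonic_noise_sd: float = 0.02
    unit_scale: float = DEFAULT_UNIT_SCALE
    gsd: float = 0.1
    dsm_noise_sd: float = 0.02
    dsm_canopy_error_sd: float = 0.05
    soil_fraction: float = 0.4
    dtm_method: str = "kriging"
    reference_noise_sd: float = 0.01
    n_reference_replicates: int = 3

    def validate(self) -> None:
        self.scene.validate()
        if len(self.campaigns) != len(self.growth_factors):
            raise ValueError("one growth factor per campaign required")
        for c in self.campaigns:
            if c not in CAMPAIGN_METHODS:
                raise ValueError(f"campaign index {c} outside 1..5")


@dataclass
class StudyResult:
    """Tables and summaries produced by one simulation study."""

    lidar_estimates: pd.DataFrame
    raw_vs_processed: pd.DataFrame
    category_table: pd.DataFrame
    sensor_summary: pd.DataFrame
    derived_stats: dict
    references: pd.DataFrame
    seeds: dict


def scan_centers(plots_per_row: int) -> list[int]:
    """Columns at which the cart stops so every plot is covered.

    Scans sit every third column starting at column 1; if the last column
    is left uncovered an extra stop one short of the row end covers it.
    """
    if plots_per_row < 3:
        raise ValueError("a row needs at least 3 plots for three-plot scans")
    centers = list(range(1, plots_per_row - 1, 3))
    covered = set()
    for c in centers:
        covered.update((c - 1, c, c + 1))
    if plots_per_row - 1 not in covered:
        centers.append(plots_per_row - 2)
    return centers


def _draw_pose(rng: np.random.Generator, config: StudyConfig) -> ScanPose:
    sr, sp, sy = config.pose_sd_deg
    roll, pitch, yaw = (
        float(np.clip(rng.normal(0, s), -10, 10)) if s > 0 else 0.0
        for s in (sr, sp, sy)
    )
    return ScanPose(roll=roll, pitch=pitch, yaw=yaw, sensor_height=config.sensor_height)


def lidar_plot_ladders(
    cloud: PointCloud,
    plot_ids: tuple[int, int, int],
    plot_width: float,
    sensor_height: float,
    processed: bool = True,
    baseline_strategy: str = "histogram_peak",
    step: float = LIDAR_STEP,
) -> dict[int, PercentileLadder]:
    """One scan's plot ladders: trim, (optionally) correct tilt, re-baseline,
    split, and build each plot's cumulative Z percentile ladder."""
    work = trim_cloud(cloud, plot_width)
    if processed:
        work, _ = correct_tilt(work)
    work, _ = correct_ground_baseline(
        work, strategy=baseline_strategy, sensor_height=sensor_height
    )
    parts = split_cloud(work, plot_width, plot_ids=plot_ids)
    return {
        part.plot_id: percentile_ladder(part.cloud.z, step=step, plot_id=part.plot_id)
        for part in parts
        if len(part) > 0
    }


def run_lidar_campaign(
    scene: FieldScene,
    campaign: int,
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Scan every row of the field and return per-plot ladder rows.

    Each plot keeps its first estimate (plots covered by two overlapping
    stops are not re-estimated). The returned frame has one row per plot and
    percentile level, for both the processed and the raw route.
    """
    cfg = scene.config
    nrows = int(np.ceil(scene.n_plots / cfg.plots_per_row))
    rows = []
    seen: set[int] = set()
    for row in range(nrows):
        for col in scan_centers(cfg.plots_per_row):
            middle = row * cfg.plots_per_row + col
            if middle + 1 >= scene.n_plots:
                continue
            pose = _draw_pose(rng, config)
            scan_seed = int(rng.integers(0, 2**31 - 1))
            cloud, records = simulate_lidar_scan(
                scene,
                middle,
                pose,
                density=config.lidar_density,
                ground_fraction=config.ground_fraction,
                noise_sd=config.lidar_noise_sd,
                seed=scan_seed,
            )
            plot_ids = (middle - 1, middle, middle + 1)
            processed = lidar_plot_ladders(
                cloud, plot_ids, cfg.plot_width, pose.sensor_height,
                processed=True, baseline_strategy=config.baseline_strategy,
            )
            raw = lidar_plot_ladders(
                cloud, plot_ids, cfg.plot_width, pose.sensor_height,
                processed=False, baseline_strategy="sensor_height",
            )
            for rec in records:
                if rec.plot_id in seen:
                    continue
                seen.add(rec.plot_id)
                lad_p = processed.get(rec.plot_id)
                lad_r = raw.get(rec.plot_id)
                if lad_p is None or lad_r is None:
                    logger.warning(
                        "campaign %d plot %d: empty plot cloud, skipped",
                        campaign, rec.plot_id,
                    )
                    continue
                rows.append(
                    {
                        "campaign": campaign,
                        "plot_id": rec.plot_id,
                        "position": rec.position,
                        "true_percentile": rec.empirical_true_percentile,
                        "ladder": lad_p,
                        "raw_ladder": lad_r,
                    }
                )
    return pd.DataFrame(rows)


def run_uas_campaign(
    scene: FieldScene,
    campaign: int,
    config: StudyConfig,
    rng: np.random.Generator,
) -> dict[int, PercentileLadder]:
    """Simulate the campaign's DSM, build the height map, extract ladders."""
    dsm_seed = int(rng.integers(0, 2**31 - 1))
    soil_seed = int(rng.integers(0, 2**31 - 1))
    dsm, soil_mask = simulate_dsm(
        scene,
        gsd=config.gsd,
        noise_sd=config.dsm_noise_sd,
        canopy_error_sd=config.dsm_canopy_error_sd,
        seed=dsm_seed,
    )
    samples = sample_soil_pixels(dsm, soil_mask, fraction=config.soil_fraction, seed=soil_seed)
    dtm = interpolate_dtm(samples, dsm, method=config.dtm_method)
    hmap = height_map(dsm, dtm)
    polygons = {
        f["properties"]["plot_id"]: shapely.geometry.shape(f["geometry"])
        for f in build_plot_polygons(scene)["features"]
    }
    ladders = {}
    for pid, poly in polygons.items():
        values = plot_pixel_values(hmap, poly)
        ladders[pid] = percentile_ladder(values, step=UAS_STEP, source="uas", plot_id=pid)
    return ladders


def run_simulation_study(
    config: StudyConfig | None = None, seed: int = 0
) -> StudyResult:
    """Run the full synthetic study and assemble the comparison report."""
    config = StudyConfig() if config is None else config
    config.validate()
    master = np.random.default_rng(seed)
    scene_seed = int(master.integers(0, 2**31 - 1))
    base_scene = generate_field_scene(config.scene, seed=scene_seed)
    logger.info("study seed=%s scene_seed=%s n_plots=%d", seed, scene_seed, base_scene.n_plots)

    lidar_frames = []
    uas_rows = []
    us_rows = []
    refs = []
    for campaign, growth in zip(config.campaigns, config.growth_factors):
        scene = dataclasses.replace(
            base_scene, true_height=base_scene.true_height * growth
        )
        method = CAMPAIGN_METHODS[campaign]
        crng = np.random.default_rng(master.integers(0, 2**31 - 1))
        refs.append(
            generate_reference_heights(
                scene, campaign, method,
                n_replicates=config.n_reference_replicates,
                noise_sd=config.reference_noise_sd,
                seed=int(crng.integers(0, 2**31 - 1)),
            )
        )
        frame = run_lidar_campaign(scene, campaign, config, crng)
        lidar_frames.append(frame)
        for pid, lad in run_uas_campaign(scene, campaign, config, crng).items():
            uas_rows.append({"campaign": campaign, "plot_id": pid, "ladder": lad})
        for pid in range(scene.n_plots):
            pose = _draw_pose(crng, config)
            voltage = simulate_ultrasonic(
                scene, pid, pose,
                echo_depth_percentile=config.echo_depth_percentile,
                noise_sd=config.ultrasonic_noise_sd,
                seed=int(crng.integers(0, 2**31 - 1)),
                unit_scale=config.unit_scale,
            )
            h_c = ultrasonic_height(
                pose.sensor_height, ultrasonic_distance(voltage), config.unit_scale
            )
            us_rows.append(
                {"campaign": campaign, "plot_id": pid, "voltage_V": voltage, "height_m": h_c}
            )
        logger.info("campaign %d (method %s): %d lidar plots", campaign, method, len(frame))

    lidar = pd.concat(lidar_frames, ignore_index=True)
    uas = pd.DataFrame(uas_rows)
    ultrasonic = pd.DataFrame(us_rows)
    references = pd.concat(refs, ignore_index=True)
    result = build_comparison_report(lidar, uas, ultrasonic, references)
    result.seeds.update({"master": int(seed), "scene": scene_seed})
    return result


def _ref_lookup(references: pd.DataFrame) -> dict:
    return {
        (int(r.campaign), int(r.plot_id)): float(r.height_m)
        for r in references.itertuples()
    }


def _select(frame: pd.DataFrame, refmap, campaigns, position=None):
    sel = frame[frame.campaign.isin(campaigns)]
    if position is not None:
        sel = sel[sel.position == position]
    ladders, refs = [], []
    missing = []
    for r in sel.itertuples():
        key = (int(r.campaign), int(r.plot_id))
        if key not in refmap:
            missing.append(key)
            continue
        ladders.append(r.ladder)
        refs.append(refmap[key])
    return ladders, np.asarray(refs), missing


def build_comparison_report(
    lidar: pd.DataFrame,
    uas: pd.DataFrame,
    ultrasonic: pd.DataFrame | None,
    references: pd.DataFrame,
) -> StudyResult:
    """Assemble the evaluation tables from per-plot estimates.

    ``lidar`` needs columns campaign, plot_id, position, ladder (and
    optionally raw_ladder); ``uas`` campaign, plot_id, ladder; ``ultrasonic``
    campaign, plot_id, height_m (may be None or empty — the remaining
    sensors are still reported). Plots without a reference height are listed
    in the derived stats, not fatal.
    """
    refmap = _ref_lookup(references)
    campaigns = sorted(references.campaign.unique())
    cat_campaigns = {
        "A": [c for c in campaigns if CAMPAIGN_METHODS[c] == "A"],
        "B": [c for c in campaigns if CAMPAIGN_METHODS[c] == "B"],
        "all": list(campaigns),
    }
    missing_refs: list = []

    # --- raw versus processed, per campaign -------------------------------
    rvp_rows = []
    has_raw = "raw_ladder" in lidar.columns and lidar["raw_ladder"].notna().all()
    for c in campaigns:
        ladders, refs, miss = _select(lidar, refmap, [c])
        missing_refs += miss
        if not ladders:
            continue
        p_pct, p_rmse = optimal_percentile(ladders, refs)
        row = {
            "campaign": int(c),
            "processed_min_rmse": p_rmse,
            "processed_optimal_percentile": p_pct,
        }
        if has_raw:
            raw_sel = lidar[lidar.campaign == c]
            raw_ladders = [r.raw_ladder for r in raw_sel.itertuples() if (int(r.campaign), int(r.plot_id)) in refmap]
            r_pct, r_rmse = optimal_percentile(raw_ladders, refs)
            row.update(
                {
                    "raw_min_rmse": r_rmse,
                    "raw_optimal_percentile": r_pct,
                    "rmse_reduction_pct": percent_reduction(r_rmse, p_rmse),
                }
            )
        rvp_rows.append(row)
    raw_vs_processed = pd.DataFrame(rvp_rows)

    # --- method-category and plot-position breakdown ----------------------
    cat_rows = []
    for cat, cset in cat_campaigns.items():
        for pos in (None, "side", "middle"):
            ladders, refs, miss = _select(lidar, refmap, cset, pos)
            missing_refs += miss
            if not ladders:
                continue
            pct, mrmse = optimal_percentile(ladders, refs)
            try:
                r2_pct, r2_max = optimal_r2_percentile(ladders, refs)
            except ValueError:
                r2_pct, r2_max = np.nan, np.nan
            cat_rows.append(
                {
                    "category": cat,
                    "position": pos or "pooled",
                    "n_plots": len(ladders),
                    "min_rmse": mrmse,
                    "optimal_percentile": pct,
                    "max_r2": r2_max,
                    "max_r2_percentile": r2_pct,
                }
            )
    category_table = pd.DataFrame(cat_rows)

    derived: dict = {}
    ct = (
        category_table.set_index(["category", "position"])
        if not category_table.empty
        else category_table
    )
    if not category_table.empty and {"A", "B", "all"} <= set(category_table.category):
        derived["all_vs_A_pct"] = percent_exceed(
            ct.loc[("all", "pooled"), "min_rmse"], ct.loc[("A", "pooled"), "min_rmse"]
        )
        derived["all_vs_B_pct"] = percent_exceed(
            ct.loc[("all", "pooled"), "min_rmse"], ct.loc[("B", "pooled"), "min_rmse"]
        )
        try:
            derived["avg_rmse_increase_m"] = average_rmse_increase(
                [
                    (
                        ct.loc[(cat, "pooled"), "min_rmse"],
                        ct.loc[(cat, "side"), "min_rmse"],
                        ct.loc[(cat, "middle"), "min_rmse"],
                    )
                    for cat in ("A", "B")
                ]
            )
        except KeyError:
            pass

    # --- pooled sensor comparison at per-category optimal percentiles ----
    sensor_rows = []
    chosen: dict[str, dict] = {}
    for name, frame in (("lidar", lidar), ("uas", uas)):
        if frame is None or frame.empty:
            continue
        est, ref_v = [], []
        chosen[name] = {}
        for cat in ("A", "B"):
            cset = cat_campaigns[cat]
            ladders, refs, miss = _select(frame, refmap, cset)
            missing_refs += miss
            if not ladders:
                continue
            pct, _ = optimal_percentile(ladders, refs)
            chosen[name][cat] = pct
            est += [lad.height_at(pct) for lad in ladders]
            ref_v += list(refs)
        if est:
            res = evaluate(est, ref_v)
            sensor_rows.append(
                {
                    "sensor": name,
                    "n": res.n,
                    "rmse": res.rmse,
                    "bias": res.bias,
                    "r_squared": res.r_squared,
                }
            )
    if ultrasonic is not None and not ultrasonic.empty:
        pairs = [
            (float(r.height_m), refmap[(int(r.campaign), int(r.plot_id))])
            for r in ultrasonic.itertuples()
            if (int(r.campaign), int(r.plot_id)) in refmap
        ]
        if pairs:
            est, ref_v = zip(*pairs)
            res = evaluate(est, ref_v)
            sensor_rows.append(
                {
                    "sensor": "ultrasonic",
                    "n": res.n,
                    "rmse": res.rmse,
                    "bias": res.bias,
                    "r_squared": res.r_squared,
                }
            )
    else:
        derived["ultrasonic"] = "absent"
    sensor_summary = pd.DataFrame(sensor_rows)
    derived["chosen_percentiles"] = chosen
    derived["missing_references"] = sorted(set(missing_refs))

    lidar_out = lidar.drop(columns=[c for c in ("ladder", "raw_ladder") if c in lidar], errors="ignore")
    return StudyResult(
        lidar_estimates=lidar_out,
        raw_vs_processed=raw_vs_processed,
        category_table=category_table,
        sensor_summary=sensor_summary,
        derived_stats=derived,
        references=references,
        seeds={},
    )


def ladders_long(frame: pd.DataFrame, ladder_column: str = "ladder") -> pd.DataFrame:
    """Flatten a ladder frame to long CSV form (one row per percentile level)."""
    rows = []
    for r in frame.itertuples():
        lad = getattr(r, ladder_column)
        for p, h in zip(lad.percentiles, lad.heights):
            rows.append(
                {
                    "campaign": int(r.campaign),
                    "plot_id": int(r.plot_id),
                    "position": getattr(r, "position", "pooled"),
                    "percentile": float(p),
                    "height_m": float(h),
                }
            )
    return pd.DataFrame(rows)


def long_to_ladders(long_df: pd.DataFrame, source: str = "lidar") -> pd.DataFrame:
    """Rebuild a ladder frame (campaign, plot_id, position, ladder) from long form."""
    need = {"campaign", "plot_id", "percentile", "height_m"}
    if not need <= set(long_df.columns):
        raise ValueError(f"ladder table needs columns {sorted(need)}")
    rows = []
    for (campaign, pid), grp in long_df.groupby(["campaign", "plot_id"], sort=True):
        grp = grp.sort_values("percentile")
        rows.append(
            {
                "campaign": int(campaign),
                "plot_id": int(pid),
                "position": grp["position"].iloc[0] if "position" in grp else "pooled",
                "ladder": PercentileLadder(
                    grp["percentile"].to_numpy(),
                    grp["height_m"].to_numpy(),
                    source=source,
                    plot_id=int(pid),
                ),
            }
        )
    return pd.DataFrame(rows)


def run_sensor_comparison(
    reference_csv,
    lidar_ladders_csv=None,
    uas_ladders_csv=None,
    ultrasonic_csv=None,
    outdir=None,
) -> StudyResult:
    """Evaluate user-supplied per-sensor files through the same report path.

    Inputs are the persisted forms of the pipeline outputs: long-form ladder
    CSVs for LiDAR and UAS, an ultrasonic table with ``campaign, plot_id,
    height_m``, and the reference heights. Absent sensors are skipped and
    marked absent in the report rather than failing.
    """
    references = pd.read_csv(reference_csv)
    need = {"campaign", "plot_id", "height_m"}
    if not need <= set(references.columns):
        raise ValueError(f"{reference_csv}: reference table needs columns {sorted(need)}")
    lidar = (
        long_to_ladders(pd.read_csv(lidar_ladders_csv), source="lidar")
        if lidar_ladders_csv
        else pd.DataFrame(columns=["campaign", "plot_id", "position", "ladder"])
    )
    uas = (
        long_to_ladders(pd.read_csv(uas_ladders_csv), source="uas")
        if uas_ladders_csv
        else pd.DataFrame(columns=["campaign", "plot_id", "ladder"])
    )
    ultrasonic = None
    if ultrasonic_csv:
        ultrasonic = pd.read_csv(ultrasonic_csv)
        if not need <= set(ultrasonic.columns):
            raise ValueError(f"{ultrasonic_csv}: ultrasonic table needs columns {sorted(need)}")
    result = build_comparison_report(lidar, uas, ultrasonic, references)
    if outdir is not None:
        write_report(result, outdir)
    return result


def write_report(result: StudyResult, outdir) -> None:
    """Persist the report bundle as CSV tables plus a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.raw_vs_processed.to_csv(out / "raw_vs_processed.csv", index=False, float_format="%.6g")
    result.category_table.to_csv(out / "category_table.csv", index=False, float_format="%.6g")
    result.sensor_summary.to_csv(out / "sensor_summary.csv", index=False, float_format="%.6g")
    result.lidar_estimates.to_csv(out / "lidar_estimates.csv", index=False, float_format="%.6g")
    result.references.to_csv(out / "reference_heights.csv", index=False, float_format="%.6g")
    c3dio.write_json(
        {"derived_stats": result.derived_stats, "seeds": result.seeds},
        out / "summary.json",
    )
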