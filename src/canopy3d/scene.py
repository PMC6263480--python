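"""Synthetic wheat-field scenes and simulated sensor outputs.

The study's field data are not public, so every downstream stage is
exercised against a simulator whose ground truth is recorded at generation
time. A scene is a rectangular field of plots on sloped, gently rough
terrain; each plot carries a true plant height. From a scene the module
produces:

* static LiDAR scans — three adjacent plots per scan (a middle plot under
  the sensor and two side plots), with a known cart pose applied, so that
  tilt correction can be validated by round trip;
* ultrasonic voltages — the echo forms at a configurable depth percentile of
  the canopy inside the sensor's cone footprint, and the voltage is the
  exact inverse of the distance calibration;
* a canopy-top DSM raster with a known soil mask;
* reference heights — the mean of a few noisy replicate measurements per
  plot, mimicking yardstick readings.

Canopy micro-structure is not described by any field protocol, so it is
modeled as a truncated normal of plant-element heights on
``[0, 1.05 * H]`` with mean ``0.85 * H`` and standard deviation
``height_sd_fraction * H``: the true plant height ``H`` then sits at a high
but sub-100th percentile of the element heights, as canopy percentile
methods assume. The degenerate ``height_sd_fraction = 0`` limit collapses
the canopy to a uniform sward at exactly ``H``.

Within-plot LiDAR points are drawn as balanced area samples: each draw is
mirrored about the plot center in x and the scan line in y (four copies
sharing one height), which removes the finite-sample cross-plane
covariances of the untilted scene so that recovered tilt reflects the
applied pose rather than sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cloud import PointCloud
from .heights import (
    DEFAULT_CALIBRATION,
    DEFAULT_UNIT_SCALE,
    CalibrationCoefficients,
    empirical_percentile,
)
from .raster import Raster

#: Points per plot in one static scan, by position (middle plots sit under
#: the sensor and are denser).
DEFAULT_DENSITY = {"side": 6000, "middle": 8000}

#: Fraction of a plot's LiDAR returns that come from the ground.
DEFAULT_GROUND_FRACTION = 0.3

#: Ultrasonic cone half-angle, degrees (14 deg full field of view).
ULTRASONIC_HALF_ANGLE = 7.0


class ConfigError(ValueError):
    """A scene configuration value violates its invariant."""


class GenerationError(RuntimeError):
    """A sensor simulation could not produce a usable output."""


@dataclass
class TerrainConfig:
    """Ground surface: planar slopes plus smooth low-amplitude roughness."""

    slope_x: float = 0.01
    slope_y: float = 0.005
    roughness_sd: float = 0.01

    def validate(self) -> None:
        if self.roughness_sd < 0:
            raise ConfigError("terrain.roughness_sd must be non-negative")


@dataclass
class CanopyConfig:
    """Canopy cover and within-plot height spread."""

    cover_fraction: float = 0.85
    height_sd_fraction: float = 0.08

    def validate(self) -> None:
        if not 0 <= self.cover_fraction <= 1:
            raise ConfigError("canopy.cover_fraction must lie in [0, 1]")
        if self.height_sd_fraction < 0:
            raise ConfigError("canopy.height_sd_fraction must be non-negative")


@dataclass
class SceneConfig:
    """Field geometry and crop statistics for scene generation.

    ``plot_width`` is the center-to-center distance of adjacent alleyways
    (1.524 m in the study); plots are laid out on a ``plots_per_row`` grid.
    ``height_range`` bounds the per-plot true heights (meters).
    """

    plot_width: float = 1.524
    n_plots: int = 100
    plots_per_row: int = 10
    plot_length: float = 1.5
    canopy_width: float = 1.2
    row_pitch: float = 2.0
    height_range: tuple[float, float] = (0.4, 1.0)
    terrain: TerrainConfig = field(default_factory=TerrainConfig)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)

    def validate(self) -> None:
        if self.plot_width <= 0:
            raise ConfigError("plot_width must be positive")
        if self.n_plots < 1:
            raise ConfigError("n_plots must be at least 1")
        if not 1 <= self.plots_per_row <= self.n_plots:
            raise ConfigError("plots_per_row must lie in [1, n_plots]")
        if self.plot_length <= 0:
            raise ConfigError("plot_length must be positive")
        if not 0 < self.canopy_width <= self.plot_width:
            raise ConfigError("canopy_width must lie in (0, plot_width]")
        if self.row_pitch < self.plot_length:
            raise ConfigError("row_pitch must be at least plot_length")
        lo, hi = self.height_range
        if lo < 0 or hi < lo:
            raise ConfigError("height_range must satisfy 0 <= lo <= hi")
        self.terrain.validate()
        self.canopy.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "SceneConfig":
        data = dict(data)
        if "terrain" in data and isinstance(data["terrain"], dict):
            data["terrain"] = TerrainConfig(**data["terrain"])
        if "canopy" in data and isinstance(data["canopy"], dict):
            data["canopy"] = CanopyConfig(**data["canopy"])
        if "height_range" in data:
            data["height_range"] = tuple(data["height_range"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown scene configuration fields: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ScanPose:
    """Cart attitude and sensor mounting height for one static scan."""

    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    sensor_height: float = 2.0

    def __post_init__(self) -> None:
        for name in ("roll", "pitch", "yaw"):
            if abs(getattr(self, name)) > 30:
                raise ConfigError(f"|{name}| must not exceed 30 degrees")
        if self.sensor_height <= 0:
            raise ConfigError("sensor_height must be positive")

    def rotation(self) -> np.ndarray:
        """World-to-sensor rotation Rz(yaw) @ Ry(pitch) @ Rx(roll)."""
        from .correction import rotation_matrix

        return (
            rotation_matrix("z", self.yaw)
            @ rotation_matrix("y", self.pitch)
            @ rotation_matrix("x", self.roll)
        )


@dataclass
class GroundTruthRecord:
    """Per-plot generation truth for one simulated scan."""

    plot_id: int
    position: str
    true_height: float
    empirical_true_percentile: float
    applied_pose: ScanPose
    n_points: int


@dataclass
class FieldScene:
    """A generated field: configuration, per-plot true heights, terrain."""

    config: SceneConfig
    true_height: np.ndarray
    seed: int
    _phases: np.ndarray = field(repr=False, default_factory=lambda: np.zeros(3))

    @property
    def n_plots(self) -> int:
        return self.config.n_plots

    @property
    def plot_width(self) -> float:
        return self.config.plot_width

    def plot_rowcol(self, plot_id: int) -> tuple[int, int]:
        return divmod(int(plot_id), self.config.plots_per_row)

    def plot_center(self, plot_id: int) -> tuple[float, float]:
        row, col = self.plot_rowcol(plot_id)
        return col * self.config.plot_width, row * self.config.row_pitch

    def terrain_elevation(self, x, y):
        """Deterministic ground elevation: slopes plus smooth roughness.

        Roughness is a fixed-phase sum of three long-period sinusoids scaled
        so its pointwise standard deviation equals ``roughness_sd``; periods
        exceed one scan's footprint so the within-scan surface is nearly
        planar, matching the assumption that slope variation across three
        adjacent plots is negligible.
        """
        t = self.config.terrain
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = t.slope_x * x + t.slope_y * y
        if t.roughness_sd > 0:
            amp = t.roughness_sd * np.sqrt(2.0 / 3.0)
            p1, p2, p3 = 7.3, 11.1, 9.4
            z = z + amp * (
                np.sin(2 * np.pi * x / p1 + self._phases[0])
                + np.sin(2 * np.pi * y / p2 + self._phases[1])
                + np.sin(2 * np.pi * (x + y) / p3 + self._phases[2])
            )
        return z

    def field_bounds(self, margin: float = 0.5) -> tuple[float, float, float, float]:
        c = self.config
        ncols = c.plots_per_row
        nrows = int(np.ceil(c.n_plots / ncols))
        minx = -0.5 * c.plot_width - margin
        maxx = (ncols - 1) * c.plot_width + 0.5 * c.plot_width + margin
        miny = -0.5 * c.plot_length - margin
        maxy = (nrows - 1) * c.row_pitch + 0.5 * c.plot_length + margin
        return minx, miny, maxx, maxy


def generate_field_scene(config: SceneConfig | dict | None = None, seed: int = 0) -> FieldScene:
    """Draw a field scene: per-plot true heights and terrain phases.

    Deterministic: the same ``(config, seed)`` yields the identical scene.
    """
    if config is None:
        config = SceneConfig()
    elif isinstance(config, dict):
        config = SceneConfig.from_dict(config)
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.height_range
    heights = rng.uniform(lo, hi, size=config.n_plots)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    return FieldScene(config=config, true_height=heights, seed=seed, _phases=phases)


def canopy_heights(
    true_height: float, sd_fraction: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw canopy element heights for a plot of true height ``H``.

    Truncated normal on ``[0, 1.05 H]`` with mean ``0.85 H`` and sd
    ``sd_fraction * H``; degenerate at ``H`` when ``sd_fraction == 0``.
    """
    h = float(true_height)
    if h <= 0 or sd_fraction == 0:
        return np.full(n, h)
    mean, sd = 0.85 * h, sd_fraction * h
    a, b = (0.0 - mean) / sd, (1.05 * h - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _mirrored_plot_samples(
    n: int,
    half_x: float,
    half_y: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced area samples on a centered rectangle: n//4 draws mirrored
    into all four quadrants. Returns (dx, dy) of length 4 * (n // 4)."""
    q = max(1, n // 4)
    dx = rng.uniform(0, half_x, size=q)
    dy = rng.uniform(0, half_y, size=q)
    sx = np.concatenate([dx, -dx, dx, -dx])
    sy = np.concatenate([dy, dy, -dy, -dy])
    return sx, sy


def simulate_lidar_scan(
    scene: FieldScene,
    middle_plot: int,
    pose: ScanPose,
    density: dict | None = None,
    ground_fraction: float = DEFAULT_GROUND_FRACTION,
    noise_sd: float = 0.003,
    seed: int | None = None,
    return_details: bool = False,
):
    """Simulate one static three-plot LiDAR scan in the sensor frame.

    The middle plot lies directly under the sensor; its left and right
    neighbors in the same field row are the side plots. World-frame points
    (ground returns on the terrain, canopy returns at element heights above
    it) are expressed relative to the scan origin on the soil below the
    sensor, rotated by ``Rz(yaw) @ Ry(pitch) @ Rx(roll)`` and shifted down
    by the sensor height. Per-plot ground truth records the pose and the
    percentile of the above-ground height set that equals the plot's true
    height.

    Returns ``(cloud, records)``; with ``return_details=True`` a third item
    carries per-plot sample arrays for validation.
    """
    cfg = scene.config
    density = dict(DEFAULT_DENSITY if density is None else density)
    if any(v <= 0 for v in density.values()):
        raise ConfigError("density values must be positive")
    if not 0 <= ground_fraction < 1:
        raise ConfigError("ground_fraction must lie in [0, 1)")
    row, col = scene.plot_rowcol(middle_plot)
    if col < 1 or col >= cfg.plots_per_row - 1 or middle_plot + 1 >= scene.n_plots:
        raise ValueError(
            f"plot {middle_plot} has no left/right neighbors; a scan needs "
            "three contiguous plots centered on a middle plot"
        )
    rng = np.random.default_rng(seed)
    cx0, cy0 = scene.plot_center(middle_plot)
    origin_z = float(scene.terrain_elevation(cx0, cy0))
    plot_ids = (middle_plot - 1, middle_plot, middle_plot + 1)
    positions = ("side", "middle", "side")
    all_points = []
    records = []
    details = []
    for plot_id, position in zip(plot_ids, positions):
        n = int(density[position])
        if n < 10:
            raise GenerationError(
                f"plot {plot_id}: density {n} leaves fewer than 10 points"
            )
        n4 = 4 * max(1, int(round(n / 4)))
        n_ground = 4 * int(round(ground_fraction * n4 / 4))
        n_canopy = n4 - n_ground
        cx, cy = scene.plot_center(plot_id)
        gx, gy = _mirrored_plot_samples(n_ground, 0.5 * cfg.plot_width, 0.5 * cfg.plot_length, rng) if n_ground else (np.empty(0), np.empty(0))
        kx, ky = _mirrored_plot_samples(n_canopy, 0.5 * cfg.canopy_width, 0.5 * cfg.plot_length, rng) if n_canopy else (np.empty(0), np.empty(0))
        # one height and one noise value per mirror quadruple
        hq = canopy_heights(
            scene.true_height[plot_id], cfg.canopy.height_sd_fraction, max(1, n_canopy // 4), rng
        )
        h = np.tile(hq, 4)[: len(kx)]
        if noise_sd > 0:
            eps_g = np.tile(rng.normal(0, noise_sd, size=max(1, n_ground // 4)), 4)[: len(gx)]
            eps_k = np.tile(rng.normal(0, noise_sd, size=max(1, n_canopy // 4)), 4)[: len(kx)]
        else:
            eps_g = np.zeros(len(gx))
            eps_k = np.zeros(len(kx))
        x = np.concatenate([cx + gx, cx + kx])
        y = np.concatenate([cy + gy, cy + ky])
        above_ground = np.concatenate([eps_g, h + eps_k])
        z_world = scene.terrain_elevation(x, y) + above_ground
        is_ground = np.concatenate([np.ones(len(gx), bool), np.zeros(len(kx), bool)])
        try:
            pct = empirical_percentile(above_ground, scene.true_height[plot_id])
        except ValueError:
            pct = 100.0  # degenerate canopy: true height is the maximum
        records.append(
            GroundTruthRecord(
                plot_id=plot_id,
                position=position,
                true_height=float(scene.true_height[plot_id]),
                empirical_true_percentile=float(pct),
                applied_pose=pose,
                n_points=len(x),
            )
        )
        all_points.append(np.column_stack((x - cx0, y - cy0, z_world - origin_z)))
        if return_details:
            details.append(
                {
                    "plot_id": plot_id,
                    "is_ground": is_ground,
                    "above_ground": above_ground,
                    "world_local": all_points[-1].copy(),
                }
            )
    world = np.vstack(all_points)
    rot = pose.rotation()
    sensor_frame = world @ rot.T
    sensor_frame[:, 2] -= pose.sensor_height
    cloud = PointCloud(sensor_frame, frame_state="raw")
    if return_details:
        return cloud, records, details
    return cloud, records


def simulate_ultrasonic(
    scene: FieldScene,
    plot_id: int,
    pose: ScanPose,
    echo_depth_percentile: float = 25.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
    unit_scale: float = DEFAULT_UNIT_SCALE,
    calibration: CalibrationCoefficients = DEFAULT_CALIBRATION,
    echo_density: float = 250.0,
) -> float:
    """Simulate one ultrasonic voltage for a plot.

    The sensor looks down from ``sensor_height`` over the plot center with a
    7 deg half-angle cone. Canopy elements inside the footprint are sampled
    (a Poisson count at ``echo_density`` per square meter of covered canopy),
    and the echo forms at the ``echo_depth_percentile``-th percentile of
    their heights: sparse tall organs return weak echoes, so the effective
    reflector sits well below the canopy top. On a slanted cart the beam
    path to the ground lengthens to ``H_s / (cos roll * cos pitch)``, which
    produces negative apparent heights when the footprint holds no canopy.
    The returned voltage is the exact inverse of the distance calibration.
    """
    if not 0 <= echo_depth_percentile <= 100:
        raise ConfigError("echo_depth_percentile must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    cfg = scene.config
    h_s = pose.sensor_height
    radius = np.tan(np.radians(ULTRASONIC_HALF_ANGLE)) * h_s
    area = np.pi * radius**2
    lam = echo_density * cfg.canopy.cover_fraction * area
    k = int(rng.poisson(lam)) if lam > 0 else 0
    d_ground = h_s / (np.cos(np.radians(pose.roll)) * np.cos(np.radians(pose.pitch)))
    if k == 0 or scene.true_height[plot_id] <= 0:
        echo = d_ground
    else:
        heights = canopy_heights(
            scene.true_height[plot_id], cfg.canopy.height_sd_fraction, k, rng
        )
        echo = d_ground - float(np.percentile(heights, echo_depth_percentile))
    if noise_sd > 0:
        echo += rng.normal(0, noise_sd)
    voltage = (echo / unit_scale - calibration.intercept) / calibration.slope
    return float(np.clip(voltage, 0.0, 10.0))


def simulate_dsm(
    scene: FieldScene,
    gsd: float = 0.05,
    noise_sd: float = 0.02,
    canopy_error_sd: float = 0.05,
    seed: int | None = None,
    margin: float = 0.5,
) -> tuple[Raster, Raster]:
    """Simulate a photogrammetric DSM and its true soil mask.

    Each cell is the terrain elevation plus, where the cell carries canopy,
    the maximum canopy element height seen over the cell footprint (several
    plant tops project into one ground pixel, so the cell records their
    maximum), plus Gaussian per-cell surface noise. Cells without canopy
    (alleyways, borders and within-plot gaps) are soil. Canopy occupancy is
    Bernoulli(``cover_fraction``) per cell inside each plot's canopy strip.

    Photogrammetric surfaces reconstruct textured static soil well but err
    smoothly over vegetation: thin organs fall below the image resolution
    and wind moves the canopy between exposures, so the canopy surface
    carries a spatially correlated vertical error that does not average out
    within a plot and is not removed by DSM − DTM differencing (the soil,
    hence the DTM, is unaffected). This is modeled as a smooth random field
    (fixed-phase sinusoids, periods of a few meters) of pointwise standard
    deviation ``canopy_error_sd`` added to canopy cells only.

    Deterministic under the seed.
    """
    if gsd <= 0:
        raise ConfigError("gsd must be positive")
    if gsd > scene.plot_width:
        raise ConfigError("gsd exceeds the plot width; plots would be unresolvable")
    rng = np.random.default_rng(seed)
    cfg = scene.config
    minx, miny, maxx, maxy = scene.field_bounds(margin)
    ncols = int(np.ceil((maxx - minx) / gsd))
    nrows = int(np.ceil((maxy - miny) / gsd))
    origin = (minx, miny + nrows * gsd)
    xs = minx + (np.arange(ncols) + 0.5) * gsd
    ys = origin[1] - (np.arange(nrows) + 0.5) * gsd
    gx, gy = np.meshgrid(xs, ys)
    terrain = scene.terrain_elevation(gx, gy)
    col_idx = np.rint(gx / cfg.plot_width).astype(int)
    row_idx = np.rint(gy / cfg.row_pitch).astype(int)
    in_row = (row_idx >= 0) & (col_idx >= 0) & (col_idx < cfg.plots_per_row)
    plot_idx = np.where(in_row, row_idx * cfg.plots_per_row + col_idx, -1)
    valid_plot = in_row & (plot_idx < scene.n_plots)
    px = np.where(valid_plot, col_idx * cfg.plot_width, 0.0)
    py = np.where(valid_plot, row_idx * cfg.row_pitch, 0.0)
    in_strip = (
        valid_plot
        & (np.abs(gx - px) <= 0.5 * cfg.canopy_width)
        & (np.abs(gy - py) <= 0.5 * cfg.plot_length)
    )
    occupied = in_strip & (rng.random(gx.shape) < cfg.canopy.cover_fraction)
    values = terrain.copy()
    soil_mask = np.ones(gx.shape, dtype=float)
    if np.any(occupied):
        cells = np.nonzero(occupied)
        plot_of_cell = plot_idx[cells]
        heights = np.zeros(len(plot_of_cell))
        # max over a handful of element draws per cell footprint
        m = 4
        for pid in np.unique(plot_of_cell):
            sel = plot_of_cell == pid
            draws = canopy_heights(
                scene.true_height[pid],
                cfg.canopy.height_sd_fraction,
                int(sel.sum()) * m,
                rng,
            ).reshape(-1, m)
            heights[sel] = draws.max(axis=1)
        values[cells] += heights
        soil_mask[cells] = 0.0
        if canopy_error_sd > 0:
            amp = canopy_error_sd * np.sqrt(2.0 / 3.0)
            periods = rng.uniform(3.0, 9.0, size=3)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            err = amp * (
                np.sin(2 * np.pi * gx / periods[0] + phases[0])
                + np.sin(2 * np.pi * gy / periods[1] + phases[1])
                + np.sin(2 * np.pi * (gx + gy) / (periods[2] * np.sqrt(2)) + phases[2])
            )
            values[cells] += err[cells]
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=values.shape)
    dsm = Raster(values=values, origin=origin, cell_size=gsd, role="dsm")
    mask = Raster(values=soil_mask, origin=origin, cell_size=gsd, role="soil_mask")
    return dsm, mask


def generate_reference_heights(
    scene: FieldScene,
    campaign: int,
    method: str,
    n_replicates: int = 3,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Reference heights: per plot, the mean of replicate noisy measurements.

    Mirrors yardstick practice — a few measurements per plot averaged into
    one reference value, labeled with the campaign and its manual method.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be at least 1")
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0, noise_sd, size=(scene.n_plots, n_replicates))
        if noise_sd > 0
        else np.zeros((scene.n_plots, n_replicates))
    )
    return pd.DataFrame(
        {
            "plot_id": np.arange(scene.n_plots),
            "campaign": campaign,
            "method": method,
            "height_m": scene.true_height + noise.mean(axis=1),
        }
    )


def build_plot_polygons(scene: FieldScene) -> dict:
    """Plot delineations as a GeoJSON FeatureCollection of rectangles.

    Each feature is one plot's delineation (plot_width by plot_length,
    centered on the plot) carrying a ``plot_id`` property.
    """
    cfg = scene.config
    features = []
    for pid in range(scene.n_plots):
        cx, cy = scene.plot_center(pid)
        hw, hl = 0.5 * cfg.plot_width, 0.5 * cfg.plot_length
        ring = [
            [cx - hw, cy - hl],
            [cx + hw, cy - hl],
            [cx + hw, cy + hl],
            [cx - hw, cy + hl],
            [cx - hw, cy - hl],
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"plot_id": pid},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def scene_summary(scene: FieldScene) -> dict:
    """Plain-dict summary of a scene (configuration, seed, height stats)."""
    return {
        "config": asdict(scene.config),
        "seed": scene.seed,
        "n_plots": scene.n_plots,
        "true_height_min": float(scene.true_height.min()),
        "true_height_max": float(scene.true_height.max()),
    }
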