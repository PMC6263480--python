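"""Candidate plant-height extraction.

Three extraction routes feed the evaluation layer:

* cumulative Z-value percentile ladders of plot point clouds, at 0.5 %
  steps (200 candidate heights per plot);
* pixel-value percentile ladders of plant-height-map rasters inside a plot
  delineation polygon, at 1 % steps (100 candidates);
* ultrasonic heights from the lab calibration ``D = 29.116 V + 11.641``
  followed by ``H_c = H_s - D``.

The percentile grid runs over ``(0, 100]``: the 0 % endpoint is excluded so
that 0.5 % steps yield exactly 200 levels and 1 % steps exactly 100. Heights
are computed by linear interpolation between adjacent order statistics, and
the same rule is used when a ladder is evaluated at an off-grid percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .raster import Raster

#: Ladder step for LiDAR point clouds (percent) -> 200 levels.
LIDAR_STEP = 0.5
#: Ladder step for height-map rasters (percent) -> 100 levels.
UAS_STEP = 1.0


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Affine voltage-to-distance calibration of the ultrasonic sensor.

    The coefficients are used exactly as calibrated; their output unit is
    configurable downstream (see :func:`ultrasonic_height`), because the
    0-10 V signal range and the sensor's 4.27 m reach imply the calibration's
    native distance unit is two orders of magnitude smaller than a meter.
    """

    slope: float = 29.116
    intercept: float = 11.641

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


DEFAULT_CALIBRATION = CalibrationCoefficients()

#: Meters per calibration distance unit. 0.01 treats the calibration output
#: as centimeters (dimensionally consistent with the sensor's range); 1.0
#: uses the calibration exactly as printed.
DEFAULT_UNIT_SCALE = 0.01


def percentile_grid(step: float) -> np.ndarray:
    """The ladder grid ``step, 2*step, ..., 100`` for a step dividing 100."""
    if step <= 0 or step > 100:
        raise ValueError("step must lie in (0, 100]")
    n = 100.0 / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("step must divide 100")
    return np.arange(1, int(round(n)) + 1) * step


@dataclass
class PercentileLadder:
    """Ordered (percentile, height) candidates for one plot.

    Heights are non-decreasing in percentile by construction. ``source``
    records which sensing route produced the values (``lidar`` or ``uas``).
    """

    percentiles: np.ndarray
    heights: np.ndarray
    source: str = "lidar"
    plot_id: object = None

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.percentiles.shape != self.heights.shape:
            raise ValueError("percentiles and heights must align")
        if np.any(np.diff(self.percentiles) <= 0):
            raise ValueError("percentiles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.percentiles)

    def height_at(self, percentile: float) -> float:
        """Ladder height at a (possibly off-grid) percentile, interpolated."""
        return float(np.interp(percentile, self.percentiles, self.heights))


def percentile_ladder(
    values,
    step: float = LIDAR_STEP,
    source: str = "lidar",
    plot_id=None,
) -> PercentileLadder:
    """Build the cumulative percentile ladder of a set of heights.

    Each grid level's height is the linear-interpolation percentile of the
    value set (interpolating between adjacent order statistics).
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("cannot build a percentile ladder from no values")
    grid = percentile_grid(step)
    heights = np.percentile(vals, grid, method="linear")
    return PercentileLadder(grid, heights, source=source, plot_id=plot_id)


def percentile_height(values, percentile: float) -> float:
    """Linear-interpolation percentile of a value set (same rule as ladders)."""
    return float(np.percentile(np.asarray(values, dtype=float), percentile, method="linear"))


def empirical_percentile(values, height: float) -> float:
    """Inverse of :func:`percentile_height`: the percentile whose ladder
    height equals ``height``.

    Requires ``height`` to lie within the value range; the returned
    percentile round-trips through :func:`percentile_height` to machine
    precision whenever ``height`` falls on a strictly increasing segment of
    the order statistics.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    if vals.size == 0:
        raise ValueError("no values")
    if height < vals[0] or height > vals[-1]:
        raise ValueError("height lies outside the sample range")
    grid = np.linspace(0.0, 100.0, vals.size)
    return float(np.interp(height, vals, grid))


def plot_pixel_values(raster: Raster, polygon) -> np.ndarray:
    """Values of all valid cells whose center falls inside a plot polygon.

    The cell-center rule is the usual zonal-statistics convention. Centers
    exactly on the polygon boundary are included on the minimum-x and
    minimum-y edges and excluded on the opposite edges, so tiling polygons
    partition the cells.
    """
    geom = shapely.geometry.shape(polygon) if isinstance(polygon, dict) else polygon
    minx, miny, maxx, maxy = geom.bounds
    rminx, rminy, rmaxx, rmaxy = raster.bounds
    if maxx < rminx or minx > rmaxx or maxy < rminy or miny > rmaxy:
        raise ValueError(f"plot {getattr(geom, 'plot_id', '?')}: polygon outside raster extent")
    xs, ys = raster.cell_centers()
    # candidate window: cells whose center can possibly fall in the polygon
    ci = np.nonzero((xs >= minx - raster.cell_size) & (xs <= maxx + raster.cell_size))[0]
    ri = np.nonzero((ys >= miny - raster.cell_size) & (ys <= maxy + raster.cell_size))[0]
    if ci.size == 0 or ri.size == 0:
        raise ValueError("polygon covers no valid raster cells")
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    on_boundary = (
        shapely.covers(geom, shapely.points(gx.ravel(), gy.ravel())).reshape(gx.shape)
        & ~inside
    )
    if np.any(on_boundary):
        eps = 1e-9 * max(raster.cell_size, 1.0)
        lower_left = (np.abs(gx - minx) < eps) | (np.abs(gy - miny) < eps)
        inside |= on_boundary & lower_left
    window = raster.values[np.ix_(ri, ci)]
    nodata = raster.nodata_mask()[np.ix_(ri, ci)]
    valid = inside & ~nodata
    if not np.any(valid):
        raise ValueError("polygon covers no valid raster cells")
    return window[valid]


def ultrasonic_distance(
    voltage: float, coeffs: CalibrationCoefficients = DEFAULT_CALIBRATION
):
    """Convert an ultrasonic voltage to distance via the affine calibration.

    The result is in the calibration's native unit. Voltages must lie in the
    sensor's 0-10 V output range.
    """
    v = np.asarray(voltage, dtype=float)
    if np.any((v < 0) | (v > 10)):
        raise ValueError("voltage outside the sensor's 0-10 V range")
    d = coeffs.slope * v + coeffs.intercept
    return float(d) if np.isscalar(voltage) else d


def ultrasonic_height(
    sensor_height: float, distance, unit_scale: float = DEFAULT_UNIT_SCALE
):
    """Canopy height ``H_c = H_s - D`` from a sensor-to-canopy distance.

    ``unit_scale`` converts the calibration's distance unit to meters.
    Negative heights are physically meaningful (the sensor-to-ground
    distance exceeded the measured sensor height on a slanted cart) and are
    returned unchanged; callers flag them.
    """
    if sensor_height <= 0:
        raise ValueError("sensor height must be positive")
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    d = np.asarray(distance, dtype=float)
    h = sensor_height - d * unit_scale
    return float(h) if d.ndim == 0 else h


@dataclass
class UltrasonicReading:
    """One ultrasonic measurement with its derived quantities."""

    voltage: float
    sensor_height: float
    unit_scale: float = DEFAULT_UNIT_SCALE
    coeffs: CalibrationCoefficients = DEFAULT_CALIBRATION

    @property
    def distance(self) -> float:
        return ultrasonic_distance(self.voltage, self.coeffs)

    @property
    def canopy_height(self) -> float:
        return ultrasonic_height(self.sensor_height, self.distance, self.unit_scale)

    @property
    def negative(self) -> bool:
        """True when the reading implies a below-ground canopy height."""
        return self.canopy_height < 0
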