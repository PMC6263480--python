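"""Tilt and ground-baseline correction of scan point clouds.

A phenocart rolls and pitches on uneven ground, so the cloud of a static
scan is rotated with respect to the true vertical. The correction estimates
the tilt from ordinary least-squares line fits on the three coordinate-plane
projections of the cloud (z on y, z on x, y on x), converts each slope to an
angle, and counter-rotates the cloud about the corresponding axis. Because
rotations about different axes do not commute, the three-plane sweep is
iterated until every refit slope falls below a tolerance; at convergence the
result does not depend on the sweep order.

After tilt removal, Z is re-expressed as height above ground by subtracting
an estimated ground level: either the peak of a fine Z histogram over the
cloud's lower half-range (ground returns cluster sharply at the soil line)
or simply minus the measured sensor height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

#: Projection name -> (abscissa column, ordinate column).
PROJECTIONS = {"yz": (1, 2), "xz": (0, 2), "xy": (0, 1)}

#: Rotation axis that flattens each projection's fitted slope.
_PROJECTION_AXIS = {"xy": "z", "xz": "y", "yz": "x"}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class DegenerateFitError(ValueError):
    """The projection has no spread along the abscissa, so no line fits."""


def fit_projection_slope(points: np.ndarray, projection: str) -> tuple[float, float]:
    """Ordinary least squares of one coordinate on another.

    ``yz`` regresses z on y, ``xz`` regresses z on x, ``xy`` regresses y on x.
    Returns ``(slope, intercept)``.
    """
    try:
        ia, io = PROJECTIONS[projection]
    except KeyError:
        raise ValueError(f"projection must be one of {sorted(PROJECTIONS)}") from None
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    a = pts[:, ia]
    o = pts[:, io]
    if a.size < 2 or np.ptp(a) == 0:
        raise DegenerateFitError(
            f"projection {projection!r} needs >= 2 points with distinct abscissae"
        )
    am = a.mean()
    om = o.mean()
    da = a - am
    slope = float(np.dot(da, o - om) / np.dot(da, da))
    return slope, float(om - slope * am)


def slope_to_angle(slope: float) -> float:
    """Convert a fitted slope (rise over run) to an angle in degrees."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return float(np.degrees(np.arctan(slope)))


def rotation_matrix(axis: str, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a coordinate axis."""
    if axis not in _AXIS_INDEX:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotate_cloud(cloud: PointCloud, axis: str, angle_deg: float) -> PointCloud:
    """Rotate all points about the named axis through the cloud origin.

    The origin is the sensor optical center, not the centroid, so sensor
    height semantics are preserved. Lengths and pairwise distances are
    unchanged.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    rot = rotation_matrix(axis, angle_deg)
    return cloud.with_points(cloud.points @ rot.T)


def euler_zyx(rotation: np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation matrix as Rz(yaw) @ Ry(pitch) @ Rx(roll).

    Returns ``(roll, pitch, yaw)`` in degrees. Valid away from the
    gimbal-lock pitch of +-90 deg, far beyond the tilts a ground cart sees.
    """
    r = np.asarray(rotation, dtype=float)
    pitch = -np.arcsin(np.clip(r[2, 0], -1.0, 1.0))
    roll = np.arctan2(r[2, 1], r[2, 2])
    yaw = np.arctan2(r[1, 0], r[0, 0])
    return tuple(np.degrees([roll, pitch, yaw]))


@dataclass
class TiltEstimate:
    """Result of the iterative tilt correction.

    ``theta_xy``, ``theta_xz``, ``theta_yz`` are the cumulative correction
    angles applied about the z, y and x axes (degrees, sign as applied).
    ``roll``, ``pitch``, ``yaw`` are the estimated original cart tilt,
    i.e. the zyx Euler decomposition of the inverse of the net correction.
    """

    theta_xy: float
    theta_xz: float
    theta_yz: float
    iterations: int
    residual_slopes: tuple[float, float, float]
    converged: bool
    rotation: np.ndarray = field(repr=False)

    @property
    def roll(self) -> float:
        return euler_zyx(self.rotation.T)[0]

    @property
    def pitch(self) -> float:
        return euler_zyx(self.rotation.T)[1]

    @property
    def yaw(self) -> float:
        return euler_zyx(self.rotation.T)[2]

    def angles(self) -> tuple[float, float, float]:
        """Estimated (roll, pitch, yaw) of the original tilt, degrees."""
        return euler_zyx(self.rotation.T)


# Sweep order: flatten the x-y projection first (heading), then x-z (pitch
# plane), then y-z (roll plane). Iteration makes the final state independent
# of this order.
_SWEEP = ("xy", "xz", "yz")

# Rotation angle that zeroes a fitted slope s depends on the axis convention:
# about z, y' = x sin(t) + y cos(t) -> t = -atan(s)
# about y, z' = -x sin(t) + z cos(t) -> t = +atan(s)
# about x, z' = y sin(t) + z cos(t) -> t = -atan(s)
_ANGLE_SIGN = {"xy": -1.0, "xz": 1.0, "yz": -1.0}


def _flatten_projection(
    work: np.ndarray, projection: str, tolerance: float, max_inner: int = 40
) -> tuple[np.ndarray, float]:
    """Drive one projection's fitted slope below tolerance.

    The fit-and-counter-rotate step multiplies the residual covariance by
    roughly var(ordinate) / var(abscissa) per pass, so it is repeated about
    the same axis until the refit slope is flat. Should a pass ever fail to
    shrink the slope (possible when the ordinate variance rivals the
    abscissa's), the exact covariance-zeroing angle for the plane is used
    instead.
    """
    axis = _PROJECTION_AXIS[projection]
    sign = _ANGLE_SIGN[projection]
    ia, io = PROJECTIONS[projection]
    total = 0.0
    slope, _ = fit_projection_slope(work, projection)
    for _ in range(max_inner):
        if abs(slope) <= tolerance:
            break
        angle = sign * slope_to_angle(slope)
        rot = rotation_matrix(axis, angle)
        candidate = work @ rot.T
        new_slope, _ = fit_projection_slope(candidate, projection)
        if abs(new_slope) >= abs(slope):
            # exact zeroing angle for this plane's covariance (sign resolved
            # by evaluation, which keeps the axis conventions out of it)
            a = work[:, ia] - work[:, ia].mean()
            o = work[:, io] - work[:, io].mean()
            cov = float(a @ o)
            dvar = float(a @ a - o @ o)
            theta = 0.5 * np.degrees(np.arctan2(2.0 * cov, dvar))
            best = (abs(new_slope), angle, candidate, new_slope)
            for trial in (theta, -theta):
                rot = rotation_matrix(axis, trial)
                cand = work @ rot.T
                s, _ = fit_projection_slope(cand, projection)
                if abs(s) < best[0]:
                    best = (abs(s), trial, cand, s)
            _, angle, candidate, new_slope = best
            if abs(new_slope) >= abs(slope):
                break  # no improving rotation exists in this plane
        work = candidate
        total += angle
        slope = new_slope
    return work, total


def correct_tilt(
    cloud: PointCloud,
    tolerance: float = 1e-6,
    max_iterations: int = 10,
) -> tuple[PointCloud, TiltEstimate]:
    """Remove the cart tilt from a scan cloud by iterated projection fits.

    Each sweep flattens the x-y, x-z and y-z projections in turn: fit a
    least-squares line, counter-rotate the cloud about the perpendicular
    axis by the fitted slope angle, and repeat within the plane until its
    slope is flat. Sweeps repeat until all three refit slopes are below
    ``tolerance`` (in slope units) or ``max_iterations`` is reached; in the
    latter case a warning is issued and the partially corrected cloud is
    still returned, flagged as unconverged.
    """
    cloud.require_state("raw", "trimmed")
    pts = cloud.points
    if len(pts) < 3:
        raise ValueError("tilt correction needs at least 3 points")
    total = {"x": 0.0, "y": 0.0, "z": 0.0}
    net_rotation = np.eye(3)
    iterations = 0
    converged = False
    work = pts.copy()
    for iterations in range(1, max_iterations + 1):
        for projection in _SWEEP:
            axis = _PROJECTION_AXIS[projection]
            work, applied = _flatten_projection(work, projection, tolerance)
            if applied != 0.0:
                net_rotation = rotation_matrix(axis, applied) @ net_rotation
                total[axis] += applied
        residuals = tuple(fit_projection_slope(work, p)[0] for p in _SWEEP)
        if all(abs(s) <= tolerance for s in residuals):
            converged = True
            break
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if not converged:
        residuals = tuple(fit_projection_slope(work, p)[0] for p in _SWEEP)
        warnings.warn(
            f"tilt correction did not converge in {max_iterations} iterations "
            f"(residual slopes {residuals})",
            RuntimeWarning,
            stacklevel=2,
        )
    estimate = TiltEstimate(
        theta_xy=total["z"],
        theta_xz=total["y"],
        theta_yz=total["x"],
        iterations=iterations,
        residual_slopes=tuple(float(s) for s in residuals),
        converged=converged,
        rotation=net_rotation,
    )
    corrected = cloud.with_points(work, frame_state="corrected")
    return corrected, estimate


@dataclass
class GroundBaseline:
    """Estimated ground level in the corrected frame and how it was obtained."""

    ground_z: float
    strategy: str
    bin_width: float | None = None
    fallback: bool = False


def correct_ground_baseline(
    cloud: PointCloud,
    strategy: str = "histogram_peak",
    sensor_height: float | None = None,
    ground_z: float | None = None,
    bin_width: float = 0.01,
    min_lower_points: int = 50,
) -> tuple[PointCloud, GroundBaseline]:
    """Re-express Z as height above ground.

    Strategies
    ----------
    ``histogram_peak``
        Ground returns pile up at the soil line, so the most populated
        0.01 m bin of the Z histogram over the cloud's lower half-range
        locates the ground; its center becomes ``ground_z``. If fewer than
        ``min_lower_points`` points lie below the median Z the histogram is
        unreliable and the sensor-height strategy is used instead (with a
        warning), which requires ``sensor_height``.
    ``sensor_height``
        ``ground_z = -sensor_height``: the soil sits one measured sensor
        height below the origin.
    ``fixed``
        Use the caller-supplied ``ground_z`` unchanged.

    All Z values are shifted by ``-ground_z``; the cloud state advances to
    ``above_ground``.
    """
    cloud.require_state("trimmed", "corrected")
    if len(cloud) == 0:
        raise ValueError("cannot estimate a ground baseline from an empty cloud")
    fallback = False
    used_bin_width: float | None = None
    if strategy == "histogram_peak":
        z = cloud.z
        if np.count_nonzero(z < np.median(z)) < min_lower_points:
            if sensor_height is None:
                raise ValueError(
                    "histogram baseline unreliable (too few low points) and no "
                    "sensor_height available for fallback"
                )
            warnings.warn(
                "too few points below the median for a histogram baseline; "
                "falling back to the sensor-height strategy",
                RuntimeWarning,
                stacklevel=2,
            )
            strategy, fallback = "sensor_height", True
        else:
            lo = float(z.min())
            hi = lo + 0.5 * float(np.ptp(z))
            if hi <= lo:  # degenerate flat cloud
                gz = lo
            else:
                nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
                counts, edges = np.histogram(z[z <= hi], bins=nbins, range=(lo, lo + nbins * bin_width))
                peak = int(np.argmax(counts))
                gz = float(0.5 * (edges[peak] + edges[peak + 1]))
            used_bin_width = bin_width
    if strategy == "sensor_height":
        if sensor_height is None or sensor_height <= 0:
            raise ValueError("sensor_height strategy requires a positive sensor_height")
        gz = -float(sensor_height)
    elif strategy == "fixed":
        if ground_z is None or not np.isfinite(ground_z):
            raise ValueError("fixed strategy requires a finite ground_z")
        gz = float(ground_z)
    elif strategy != "histogram_peak":
        raise ValueError(f"unknown baseline strategy {strategy!r}")
    shifted = cloud.points.copy()
    shifted[:, 2] -= gz
    baseline = GroundBaseline(
        ground_z=gz, strategy=strategy, bin_width=used_bin_width, fallback=fallback
    )
    return cloud.with_points(shifted, frame_state="above_ground"), baseline
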