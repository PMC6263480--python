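"""Polar LiDAR record decoding and plot-frame windowing.

The scanner considered here is a 16-channel spinning unit: channels sit at
fixed elevation angles (-15 deg to +15 deg in 2 deg steps) and the head
sweeps in azimuth. Each return is a polar record (elevation ``omega``,
azimuth ``alpha``, range ``r``) which decodes into the device frame as

    x = r * cos(omega) * sin(alpha)
    y = r * cos(omega) * cos(alpha)
    z = r * sin(omega)

i.e. azimuth is measured from the +Y axis. A rigid mounting transform takes
the device frame to the cart frame, where the cloud is trimmed to
``|x| <= 1.5 * plot_width`` and split at ``+-0.5 * plot_width`` into a middle
plot and two side plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cloud import PlotCloud, PointCloud

#: Channel elevation angles of the 16-beam scanner, degrees.
CHANNEL_ELEVATIONS = np.arange(-15.0, 15.1, 2.0)

#: Maximum usable range, meters.
MAX_RANGE = 100.0

RECORD_COLUMNS = ("omega_deg", "azimuth_deg", "range_m")


class InvalidRecordError(ValueError):
    """A polar record violates the sensor's physical envelope."""


def _record_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a DataFrame with the standard columns or a (n, 3) array."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        return (
            records["omega_deg"].to_numpy(float),
            records["azimuth_deg"].to_numpy(float),
            records["range_m"].to_numpy(float),
        )
    arr = np.atleast_2d(np.asarray(records, dtype=float))
    if arr.shape[1] != 3:
        raise ValueError("records array must have columns omega, azimuth, range")
    return arr[:, 0], arr[:, 1], arr[:, 2]


def decode_records(records) -> np.ndarray:
    """Convert polar records to device-frame Cartesian coordinates.

    Parameters
    ----------
    records
        DataFrame with columns ``omega_deg, azimuth_deg, range_m`` or an
        ``(n, 3)`` array in that column order.

    Returns
    -------
    ndarray
        ``(n, 3)`` device-frame points; ``norm(point) == range`` exactly.
    """
    omega, alpha, r = _record_arrays(records)
    if np.any(r <= 0):
        raise InvalidRecordError("range must be positive")
    if np.any(r > MAX_RANGE):
        raise InvalidRecordError(f"range exceeds the {MAX_RANGE:.0f} m envelope")
    om = np.radians(omega)
    az = np.radians(alpha)
    cos_om = np.cos(om)
    return np.column_stack(
        (r * cos_om * np.sin(az), r * cos_om * np.cos(az), r * np.sin(om))
    )


def decode_record(omega_deg: float, azimuth_deg: float, range_m: float) -> np.ndarray:
    """Decode a single polar record; see :func:`decode_records`."""
    return decode_records([[omega_deg, azimuth_deg, range_m]])[0]


def filter_fov(records: pd.DataFrame, az_lo: float, az_hi: float) -> pd.DataFrame:
    """Keep records whose azimuth lies in the half-open window ``[az_lo, az_hi)``.

    The half-open convention avoids double counting the window seam when two
    adjacent windows tile the circle. Record order is preserved; an empty
    result is allowed.
    """
    if not az_lo < az_hi:
        raise ValueError("require az_lo < az_hi")
    _, alpha, _ = _record_arrays(records)
    keep = (alpha >= az_lo) & (alpha < az_hi)
    if isinstance(records, pd.DataFrame):
        return records.loc[keep]
    return np.asarray(records)[keep]


def _check_rigid(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ValueError("mounting rotation is not orthogonal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-9):
        raise ValueError("mounting rotation is not proper (det != +1)")
    return rotation


#: Default mounting: the device spin axis is aligned with the travel axis Y,
#: so the fan of beams sweeps across the plots (X) and downward; frames
#: coincide apart from the mounting height which the caller supplies.
IDENTITY_MOUNT = (np.eye(3), np.zeros(3))


def apply_mounting(
    points: np.ndarray,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> PointCloud:
    """Map device-frame points into the cart frame with a rigid transform.

    ``p_cart = R @ p_device + t``. The transform must be proper rigid
    (orthogonal rotation with determinant +1).
    """
    rotation = _check_rigid(np.eye(3) if rotation is None else rotation)
    translation = np.zeros(3) if translation is None else np.asarray(translation, float)
    if translation.shape != (3,):
        raise ValueError("translation must be a 3-vector")
    pts = np.asarray(points, dtype=float)
    return PointCloud(pts @ rotation.T + translation, frame_state="raw")


def trim_cloud(cloud: PointCloud, plot_width: float) -> PointCloud:
    """Trim the scan in X to the three-plot window ``|x| <= 1.5 * plot_width``.

    The interval is closed, so a point exactly on the threshold is retained.
    An empty cloud trims to an empty cloud.
    """
    if plot_width <= 0:
        raise ValueError("plot_width must be positive")
    bound = 1.5 * plot_width
    keep = np.abs(cloud.x) <= bound
    return cloud.with_points(cloud.points[keep], frame_state="trimmed")


def split_cloud(
    cloud: PointCloud,
    plot_width: float,
    plot_ids: tuple[int, int, int] = (0, 1, 2),
) -> tuple[PlotCloud, PlotCloud, PlotCloud]:
    """Partition a trimmed scan at ``+-0.5 * plot_width`` into left/middle/right.

    Boundary points (``|x| == 0.5 * plot_width``) go to the middle plot.
    Every input point lands in exactly one part. The cloud must be at least
    trimmed; corrected and above-ground clouds may also be split.
    """
    if plot_width <= 0:
        raise ValueError("plot_width must be positive")
    cloud.require_state("trimmed", "corrected", "above_ground")
    half = 0.5 * plot_width
    x = cloud.x
    in_middle = np.abs(x) <= half
    in_left = x < -half
    in_right = x > half
    state = cloud.frame_state
    left_id, mid_id, right_id = plot_ids
    return (
        PlotCloud(left_id, "side", PointCloud(cloud.points[in_left], state)),
        PlotCloud(mid_id, "middle", PointCloud(cloud.points[in_middle], state)),
        PlotCloud(right_id, "side", PointCloud(cloud.points[in_right], state)),
    )
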