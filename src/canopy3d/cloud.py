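"""Point-cloud containers shared by the geometry, correction and extraction stages.

A :class:`PointCloud` is a bag of Cartesian points in the cart frame: the
origin sits at the sensor optical center, X runs across the plots toward
increasing plot index, Y runs along the direction of travel, and Z points up.
Clouds move through an ordered sequence of processing states, and operations
downstream check the state so that, for instance, heights are never extracted
from a cloud that is still expressed relative to the sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Forward-only processing states, in order.
FRAME_STATES = ("raw", "trimmed", "corrected", "above_ground")

#: Plot positions within one static scan.
POSITIONS = ("side", "middle")


class FrameStateError(RuntimeError):
    """An operation was applied to a cloud in the wrong processing state."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


@dataclass
class PointCloud:
    """Cartesian 3D points in the cart frame plus their processing state.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of x, y, z in meters.
    frame_state
        One of ``raw``, ``trimmed``, ``corrected``, ``above_ground``;
        transitions only move forward through that list.
    """

    points: np.ndarray
    frame_state: str = "raw"

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.frame_state not in FRAME_STATES:
            raise ValueError(f"unknown frame_state {self.frame_state!r}")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def state_index(self) -> int:
        return FRAME_STATES.index(self.frame_state)

    def require_state(self, *allowed: str) -> None:
        if self.frame_state not in allowed:
            raise FrameStateError(
                f"cloud is in state {self.frame_state!r}; expected one of {allowed}"
            )

    def with_points(self, points: np.ndarray, frame_state: str | None = None) -> "PointCloud":
        """Return a new cloud, optionally advancing the processing state."""
        state = self.frame_state if frame_state is None else frame_state
        if FRAME_STATES.index(state) < self.state_index():
            raise FrameStateError(
                f"cannot move backward from {self.frame_state!r} to {state!r}"
            )
        return PointCloud(points=np.array(points, dtype=float), frame_state=state)

    def copy(self) -> "PointCloud":
        return replace(self, points=self.points.copy())


@dataclass
class PlotCloud:
    """The slice of a scan cloud that belongs to a single plot.

    ``middle`` plots satisfy ``|x| <= plot_width / 2``; ``side`` plots fill
    the remainder of the trimmed scan out to ``1.5 * plot_width``.
    """

    plot_id: int
    position: str
    cloud: PointCloud = field(repr=False)

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")

    def __len__(self) -> int:
        return len(self.cloud)
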