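"""Core data containers for needle-driving trials.

A trial is one pass of a curved surgical needle through soft tissue,
recorded as synchronized time series of tooltip pose (position + unit
quaternion), gripper state, and tissue-interaction force/torque measured
by a sensor mounted beneath the tissue.  The tissue frame is right-handed
with ``z`` normal to the tissue face; quaternions are scalar-first
``(w, x, y, z)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import shapely

__all__ = [
    "SubtaskLabel",
    "TrialRecording",
    "UniformTrial",
    "TissueGeometry",
    "SegmentedTrial",
]

_QUAT_NORM_TOL = 1e-9


class SubtaskLabel(enum.IntEnum):
    """Per-sample subtask classes of a needle-driving trial."""

    OUTSIDE = 0
    INSERTION = 1
    CORRECTION = 2
    REPOSITION = 3
    EXTRACTION = 4


@dataclass
class TrialRecording:
    """One trial's synchronized raw time series.

    Parameters
    ----------
    t : (N,) timestamps in seconds, strictly increasing.
    position : (N, 3) tooltip position, m.
    orientation : (N, 4) unit quaternions, scalar-first (w, x, y, z).
    gripper : (N,) gripper state; *closed* when at or below the
        configured gripper threshold (jaw-angle-like convention).
    force : (N, 3) tissue interaction force, N.
    torque : (N, 3) tissue interaction torque, N·m.
    meta : free-form metadata (participant, condition, setup, phase,
        block, trial index, native rate in Hz, ...).
    """

    t: np.ndarray
    position: np.ndarray
    orientation: np.ndarray
    gripper: np.ndarray
    force: np.ndarray
    torque: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.orientation = np.atleast_2d(np.asarray(self.orientation, dtype=float))
        self.gripper = np.asarray(self.gripper, dtype=float)
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        self.torque = np.atleast_2d(np.asarray(self.torque, dtype=float))
        n = self.t.shape[0]
        for name in ("position", "orientation", "gripper", "force", "torque"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(
                    f"channel {name!r} has {arr.shape[0]} samples, expected {n}"
                )
        if self.position.shape[1] != 3 or self.force.shape[1] != 3 or self.torque.shape[1] != 3:
            raise ValueError("position/force/torque must be (N, 3)")
        if self.orientation.shape[1] != 4:
            raise ValueError("orientation must be (N, 4) scalar-first quaternions")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        qn = np.linalg.norm(self.orientation, axis=1)
        if np.any(np.abs(qn - 1.0) > 1e-6):
            raise ValueError("orientation quaternions must be unit-norm")
        if np.any(np.abs(qn - 1.0) > _QUAT_NORM_TOL):
            self.orientation = self.orientation / qn[:, None]

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def copy(self) -> "TrialRecording":
        return replace(
            self,
            t=self.t.copy(),
            position=self.position.copy(),
            orientation=self.orientation.copy(),
            gripper=self.gripper.copy(),
            force=self.force.copy(),
            torque=self.torque.copy(),
            meta=dict(self.meta),
        )


@dataclass
class UniformTrial(TrialRecording):
    """A trial resampled to a uniform grid with filtered derivatives.

    Adds velocity (m/s), acceleration (m/s²) and jerk (m/s³) channels,
    each obtained by central differencing followed by zero-phase
    low-pass filtering.
    """

    rate: float = 100.0
    velocity: np.ndarray | None = None
    acceleration: np.ndarray | None = None
    jerk: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        n = len(self)
        for name in ("velocity", "acceleration", "jerk"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_2d(np.asarray(arr, dtype=float))
                if arr.shape != (n, 3):
                    raise ValueError(f"{name} must be (N, 3)")
                setattr(self, name, arr)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclass
class TissueGeometry:
    """Tissue surface frame, outline and needle entrance/exit points.

    ``frame_origin`` and ``frame_axes`` (rows ``ex, ey, ez``) define the
    surface coordinate system with ``ez`` normal to the tissue face.
    The ``contour`` is a simple planar polygon in surface (u, v)
    coordinates (meters).  Exit points are data inputs: the *actual*
    exit point is extracted upstream (camera images in the original
    apparatus) and may be absent for open-instrument trials.
    """

    contour: np.ndarray
    entrance_point: np.ndarray
    desired_exit: np.ndarray
    actual_exit: np.ndarray | None = None
    frame_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame_axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    marker_radius: float = 0.002

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        self.entrance_point = np.asarray(self.entrance_point, dtype=float)
        self.desired_exit = np.asarray(self.desired_exit, dtype=float)
        if self.actual_exit is not None:
            self.actual_exit = np.asarray(self.actual_exit, dtype=float)
        self.frame_origin = np.asarray(self.frame_origin, dtype=float)
        self.frame_axes = np.asarray(self.frame_axes, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2 or self.contour.shape[0] < 3:
            raise ValueError("contour must be an (M>=3, 2) planar polygon")
        if not np.allclose(self.frame_axes @ self.frame_axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame_axes must be orthonormal rows")
        poly = self._polygon
        if not poly.is_valid:
            raise ValueError("contour polygon must be simple (non-self-intersecting)")
        for name in ("entrance_point", "desired_exit"):
            uv = self.to_plane(getattr(self, name)[None, :])[0]
            if not poly.buffer(1e-12).contains(shapely.Point(uv)):
                raise ValueError(f"{name} must project inside the tissue contour")

    @property
    def _polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.contour)

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """Project world points into in-plane (u, v) surface coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rel = points - self.frame_origin
        return rel @ self.frame_axes[:2].T

    def normal_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of world points along the surface normal."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.frame_origin) @ self.frame_axes[2]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: does each point's in-plane projection fall inside
        the tissue contour (boundary included)?"""
        uv = self.to_plane(points)
        poly = self._polygon.buffer(1e-12)
        return shapely.contains_xy(poly, uv[:, 0], uv[:, 1])

    def translated(self, offset: np.ndarray) -> "TissueGeometry":
        """Rigidly translate the whole geometry by ``offset`` (world frame)."""
        offset = np.asarray(offset, dtype=float)
        return TissueGeometry(
            contour=self.contour.copy(),
            entrance_point=self.entrance_point + offset,
            desired_exit=self.desired_exit + offset,
            actual_exit=None if self.actual_exit is None else self.actual_exit + offset,
            frame_origin=self.frame_origin + offset,
            frame_axes=self.frame_axes.copy(),
            marker_radius=self.marker_radius,
        )

    @property
    def d_ie(self) -> float:
        """Euclidean distance between actual entrance and exit points."""
        if self.actual_exit is None:
            raise ValueError("actual_exit not available for this trial")
        return float(np.linalg.norm(self.actual_exit - self.entrance_point))


@dataclass
class SegmentedTrial:
    """Per-sample subtask labels plus detected trial bounds.

    ``bounds`` are 0-based inclusive sample indices into ``trial``;
    ``labels`` has one entry per sample and equals ``OUTSIDE`` outside
    the bounds.
    """

    trial: UniformTrial
    bounds: tuple[int, int]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        i0, i1 = self.bounds
        n = len(self.trial)
        if not (0 <= i0 <= i1 < n):
            raise ValueError(f"bounds {self.bounds} out of range for {n} samples")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match trial length")
        if np.any(self.labels[:i0] != SubtaskLabel.OUTSIDE) or np.any(
            self.labels[i1 + 1 :] != SubtaskLabel.OUTSIDE
        ):
            raise ValueError("labels outside bounds must be OUTSIDE")

    @property
    def i_start(self) -> int:
        return self.bounds[0]

    @property
    def i_end(self) -> int:
        return self.bounds[1]

    def segment_slice(self, label: SubtaskLabel | int) -> np.ndarray:
        """Boolean mask of samples carrying ``label``."""
        return self.labels == int(label)
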