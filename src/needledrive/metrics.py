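"""Per-trial and per-subtask performance metrics.

Four metric classes quantify needle-driving performance:

* task performance — completion time, exit-point error;
* forces — total normalized force, maximum force, maximum torque about
  the tissue normal, DTW force consistency;
* kinematics — path length, circle deviation, plane deviation,
  normalized angular path, DTW trajectory consistency;
* motor-control grounded — speed–curvature–torsion power law
  ``v = alpha * kappa**beta * |tau|**gamma`` and duration-normalized
  RMS jerk (reported as log10).

Circle deviation measures how far the tooltip strays from the arc of
the needle: a plane is fitted to the path, the path is projected onto
it, a circle is fitted to the projection, and squared radial deviations
are integrated along the swept angle and normalized by the total arc
length ``Theta_arc = r * delta_theta_arc``.  Plane deviation integrates
squared point-to-plane distances along the path, normalized by path
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dtw import dtw_distance, warp_onto
from .trial import SegmentedTrial, SubtaskLabel, TissueGeometry, UniformTrial

__all__ = [
    "PlaneFit",
    "CircleFit",
    "PowerLawFit",
    "MetricVector",
    "completion_time",
    "exit_point_error",
    "total_normalized_force",
    "max_force",
    "max_torque_z",
    "dtw_consistency",
    "path_length",
    "fit_plane",
    "fit_circle",
    "circle_deviation",
    "plane_deviation",
    "angular_path",
    "curvature_torsion",
    "fit_power_law",
    "rms_jerk",
    "compute_metric_vector",
    "SCALAR_METRICS",
    "CONSISTENCY_METRICS",
    "TELEOP_ONLY_METRICS",
]

# metric names as they appear in tidy output tables
SCALAR_METRICS = (
    "completion_time",
    "exit_point_error",
    "total_normalized_force",
    "max_force",
    "max_torque_z",
    "path_length",
    "circle_deviation",
    "plane_deviation",
    "angular_path",
    "powerlaw_alpha",
    "powerlaw_beta",
    "powerlaw_gamma",
    "log_jerk",
)
CONSISTENCY_METRICS = ("force_consistency", "trajectory_consistency")
# require the camera-extracted exit point, available in teleoperation only
TELEOP_ONLY_METRICS = ("exit_point_error", "total_normalized_force")

DEFAULT_TORSION_EPS = 1e-6  # 1/m; |torsion| below this is excluded from the fit
DEFAULT_SPEED_EPS = 1e-4  # m/s


@dataclass
class PlaneFit:
    """A plane ``z = a x + b y + c`` (or its total-least-squares analog).

    ``distances`` are per-sample orthogonal point-to-plane distances.
    """

    coefficients: np.ndarray  # (a, b, c)
    normal: np.ndarray  # unit normal
    origin: np.ndarray  # a point on the plane
    distances: np.ndarray  # (N,) orthogonal distances, >= 0
    r_squared: float
    method: str = "ols"

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane basis (e1, e2)."""
        n = self.normal
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2

    def project(self, path: np.ndarray) -> np.ndarray:
        """Orthogonal projection of world points into (u, v) plane coords."""
        path = np.atleast_2d(np.asarray(path, dtype=float))
        rel = path - self.origin
        e1, e2 = self.basis()
        return np.column_stack([rel @ e1, rel @ e2])


@dataclass
class CircleFit:
    """Circle fitted to the in-plane projection of a path."""

    plane: PlaneFit
    center_uv: np.ndarray  # (2,) in plane coordinates
    radius: float
    s: np.ndarray  # (N,) signed radial deviation, m
    theta: np.ndarray  # (N,) unwrapped arc angle, rad
    residual_rms: float = 0.0

    @property
    def delta_theta_arc(self) -> float:
        """Total swept angle from first to last sample, rad."""
        return float(abs(self.theta[-1] - self.theta[0]))

    def theta_arc(self, radius: float | None = None) -> float:
        """Total arc path length ``r * delta_theta_arc`` in meters.

        Uses the fitted radius unless a nominal needle radius is given.
        """
        r = self.radius if radius is None else radius
        return float(r * self.delta_theta_arc)


@dataclass
class PowerLawFit:
    """Log-space OLS fit of the speed–curvature–torsion power law."""

    alpha: float
    beta: float
    gamma: float
    r_squared: float
    n_used: int


@dataclass
class MetricVector:
    """All per-trial(-subtask) metric values; NaN marks unavailable."""

    completion_time: float = np.nan
    exit_point_error: float = np.nan
    total_normalized_force: float = np.nan
    max_force: float = np.nan
    max_torque_z: float = np.nan
    path_length: float = np.nan
    circle_deviation: float = np.nan
    plane_deviation: float = np.nan
    angular_path: float = np.nan
    log_jerk: float = np.nan
    power_law: PowerLawFit | None = None
    force_consistency: float = np.nan
    trajectory_consistency: float = np.nan
    segment: str = "insertion"
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {
            name: getattr(self, name)
            for name in SCALAR_METRICS
            if name not in ("powerlaw_alpha", "powerlaw_beta", "powerlaw_gamma")
        }
        pl = self.power_law
        out["powerlaw_alpha"] = pl.alpha if pl is not None else np.nan
        out["powerlaw_beta"] = pl.beta if pl is not None else np.nan
        out["powerlaw_gamma"] = pl.gamma if pl is not None else np.nan
        out["force_consistency"] = self.force_consistency
        out["trajectory_consistency"] = self.trajectory_consistency
        return out


def _segment_indices(seg: SegmentedTrial, segment) -> np.ndarray:
    """Sample indices for a segment selector.

    ``segment`` is ``"bounds"`` (whole trial between detected bounds), a
    :class:`SubtaskLabel`, or its lowercase name.
    """
    if segment == "bounds":
        return np.arange(seg.i_start, seg.i_end + 1)
    if isinstance(segment, str):
        segment = SubtaskLabel[segment.upper()]
    idx = np.flatnonzero(seg.labels == int(segment))
    if idx.size == 0:
        raise ValueError(f"segment {segment!r} is empty in this trial")
    return idx


# ---------------------------------------------------------------- task class

def completion_time(seg: SegmentedTrial) -> float:
    """Trial duration ``t_end - t_start`` in seconds."""
    return float(seg.trial.t[seg.i_end] - seg.trial.t[seg.i_start])


def exit_point_error(geom: TissueGeometry) -> float:
    """In-plane distance between desired and actual needle exit, m.

    Returns NaN when the actual exit point is unavailable (open-setup
    trials, where no fixed camera extracts it).
    """
    if geom.actual_exit is None:
        return float("nan")
    duv = geom.to_plane(geom.desired_exit)[0] - geom.to_plane(geom.actual_exit)[0]
    return float(np.linalg.norm(duv))


# --------------------------------------------------------------- force class

def total_normalized_force(
    seg: SegmentedTrial, geom: TissueGeometry, segment="bounds"
) -> float:
    """Time integral of |f| over the segment divided by d_ie, N·s/m."""
    if geom.actual_exit is None:
        return float("nan")
    d_ie = geom.d_ie
    if d_ie <= 0:
        raise ValueError("entrance and exit points coincide (d_ie = 0)")
    idx = _segment_indices(seg, segment)
    fmag = np.linalg.norm(seg.trial.force[idx], axis=1)
    return float(np.trapezoid(fmag, seg.trial.t[idx]) / d_ie)


def max_force(seg: SegmentedTrial, segment="bounds") -> float:
    """Maximum force magnitude over the segment, N."""
    idx = _segment_indices(seg, segment)
    return float(np.max(np.linalg.norm(seg.trial.force[idx], axis=1)))


def max_torque_z(seg: SegmentedTrial, segment="bounds") -> float:
    """Maximum |torque| about the tissue normal, N·m.

    Ideal needle driving is planar, so this should be near zero; the
    absolute value makes the metric sign-invariant.
    """
    idx = _segment_indices(seg, segment)
    return float(np.max(np.abs(seg.trial.torque[idx, 2])))


def dtw_consistency(profiles, align: bool = True) -> float:
    """Consistency of repeated force or position profiles.

    Profiles (arrays of shape (N_i, d)) are aligned by DTW to the
    medoid profile (the one minimizing summed DTW cost to the others),
    averaged pointwise on the medoid's time base, and scored as

        (1 / N_t) * sum_i sum_n |p_i(n) - mean(n)|^2

    — zero iff all profiles are identical after alignment.  With
    ``align=False`` the profiles are compared sample-by-sample without
    warping (requires equal lengths).
    """
    profiles = [np.atleast_2d(np.asarray(p, dtype=float)) for p in profiles]
    profiles = [p if p.shape[1] > 1 or p.ndim == 2 else p for p in profiles]
    profiles = [p.reshape(p.shape[0], -1) for p in profiles]
    if len(profiles) < 2:
        raise ValueError("consistency requires at least 2 profiles")
    if any(p.shape[0] < 2 for p in profiles):
        raise ValueError("profiles must have length >= 2")
    n_t = len(profiles)

    if align:
        # pairwise DTW costs -> medoid
        costs = np.zeros((n_t, n_t))
        for i in range(n_t):
            for j in range(i + 1, n_t):
                c = dtw_distance(profiles[i], profiles[j])
                costs[i, j] = costs[j, i] = c
        medoid = int(np.argmin(costs.sum(axis=1)))
        aligned = [
            p if i == medoid else warp_onto(p, profiles[medoid])
            for i, p in enumerate(profiles)
        ]
    else:
        if len({p.shape[0] for p in profiles}) != 1:
            raise ValueError("unaligned consistency requires equal-length profiles")
        aligned = profiles

    stack = np.stack(aligned)  # (N_t, N, d)
    mean = stack.mean(axis=0)
    return float(np.sum((stack - mean) ** 2) / n_t)


# ----------------------------------------------------------- kinematic class

def path_length(path: np.ndarray) -> float:
    """Sum of consecutive Euclidean steps, m."""
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if path.shape[0] < 2:
        raise ValueError("path length requires at least 2 samples")
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def fit_plane(path: np.ndarray, method: str = "auto") -> PlaneFit:
    """Least-squares plane through a 3D path.

    ``method="ols"`` regresses z on (x, y) — the convention used when
    the movement plane is roughly upright over the tissue; it is
    undefined for (near-)vertical movement planes, whose horizontal
    footprint collapses onto a line.  ``method="tls"`` fits the
    orthogonal (total-least-squares) plane via SVD, which handles any
    orientation and is invariant under rigid motions of the scene.
    ``method="auto"`` (default) tries OLS and falls back to TLS on a
    degenerate horizontal footprint.  Orthogonal point-to-plane
    distances are reported for every method.

    Raises
    ------
    ValueError
        For fewer than 3 points, (near-)collinear paths, or an OLS fit
        of a near-vertical plane.
    """
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if path.shape[0] < 3:
        raise ValueError("plane fit requires at least 3 points")
    centroid = path.mean(axis=0)
    centered = path - centroid
    # collinearity check on the full 3D scatter
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-300):
        raise ValueError("points are (near-)collinear; plane fit is degenerate")

    if method == "auto":
        try:
            return fit_plane(path, method="ols")
        except ValueError:
            return fit_plane(path, method="tls")

    if method == "tls":
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[2]
        if normal[2] < 0:
            normal = -normal
        # express as z = a x + b y + c when representable
        if abs(normal[2]) > 1e-12:
            a, b = -normal[0] / normal[2], -normal[1] / normal[2]
            c = centroid[2] - a * centroid[0] - b * centroid[1]
        else:
            a = b = c = np.nan
        coefficients = np.array([a, b, c])
        origin = centroid
    elif method == "ols":
        design = np.column_stack([path[:, 0], path[:, 1], np.ones(path.shape[0])])
        sv_xy = np.linalg.svd(design - design.mean(axis=0), compute_uv=False)
        if sv_xy[1] < 1e-9 * max(sv_xy[0], 1e-300):
            raise ValueError(
                "path is degenerate in the horizontal plane (near-vertical plane)"
            )
        coef, *_ = np.linalg.lstsq(design, path[:, 2], rcond=None)
        a, b, c = coef
        coefficients = np.array([a, b, c])
        normal = np.array([-a, -b, 1.0])
        normal /= np.linalg.norm(normal)
        origin = np.array([centroid[0], centroid[1], a * centroid[0] + b * centroid[1] + c])
    else:
        raise ValueError(f"unknown plane-fit method {method!r}")

    distances = np.abs((path - origin) @ normal)
    z = path[:, 2]
    ss_tot = np.sum((z - z.mean()) ** 2)
    if np.isfinite(coefficients).all():
        resid = z - (coefficients[0] * path[:, 0] + coefficients[1] * path[:, 1] + coefficients[2])
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    else:
        r2 = np.nan
    return PlaneFit(
        coefficients=coefficients,
        normal=normal,
        origin=origin,
        distances=distances,
        r_squared=float(r2),
        method=method,
    )


def fit_circle(path: np.ndarray, plane: PlaneFit | None = None) -> CircleFit:
    """Fit a circle to the in-plane projection of a 3D path.

    Algebraic (Kasa) least squares seeds a geometric refinement that
    minimizes radial residuals.  The arc angle ``theta`` is unwrapped
    so a simple arc yields a monotone angle series.
    """
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if plane is None:
        plane = fit_plane(path)
    uv = plane.project(path)
    x, y = uv[:, 0], uv[:, 1]
    # algebraic seed: x^2 + y^2 = 2 cx x + 2 cy y + (r^2 - cx^2 - cy^2)
    design = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    cx, cy = sol[0], sol[1]
    r0 = float(np.sqrt(max(sol[2] + cx**2 + cy**2, 1e-300)))

    def residual(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(residual, x0=[cx, cy, r0], method="lm", xtol=1e-15, ftol=1e-15)
    cx, cy, radius = fit.x
    if radius <= 0:
        raise ValueError("circle fit produced nonpositive radius")
    dist = np.hypot(x - cx, y - cy)
    s = dist - radius
    theta = np.unwrap(np.arctan2(y - cy, x - cx))
    return CircleFit(
        plane=plane,
        center_uv=np.array([cx, cy]),
        radius=float(radius),
        s=s,
        theta=theta,
        residual_rms=float(np.sqrt(np.mean(s**2))),
    )


def circle_deviation(fit: CircleFit, radius: float | None = None) -> float:
    """Swept-angle integral of squared radial deviations, m·rad.

        (1 / Theta_arc) * sum_n s(n)^2 * |dtheta(n)|

    ``radius`` selects a nominal needle radius for the ``Theta_arc``
    normalizer; by default the fitted radius is used, keeping the
    metric self-contained when the true needle radius is unknown.
    """
    theta_arc = fit.theta_arc(radius)
    if theta_arc <= 0:
        raise ValueError("total arc path is zero; circle deviation undefined")
    dtheta = np.abs(np.diff(fit.theta))
    return float(np.sum(fit.s[1:] ** 2 * dtheta) / theta_arc)


def plane_deviation(fit: PlaneFit, path: np.ndarray) -> float:
    """Path-length integral of squared plane distances, m².

        (1 / PL) * sum_n r(n)^2 * dx(n)
    """
    path = np.atleast_2d(np.asarray(path, dtype=float))
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    pl = float(np.sum(steps))
    if pl <= 0:
        raise ValueError("zero path length; plane deviation undefined")
    return float(np.sum(fit.distances[1:] ** 2 * steps) / pl)


def quaternion_geodesic_angles(quats: np.ndarray) -> np.ndarray:
    """Rotation angle between consecutive unit quaternions, rad."""
    quats = np.atleast_2d(np.asarray(quats, dtype=float))
    dots = np.abs(np.einsum("ij,ij->i", quats[:-1], quats[1:]))
    return 2.0 * np.arccos(np.clip(dots, -1.0, 1.0))


def angular_path(quats: np.ndarray, pl: float) -> float:
    """Accumulated wrist rotation normalized by path length, rad/m."""
    if pl <= 0:
        raise ValueError("zero path length; angular path undefined")
    return float(np.sum(quaternion_geodesic_angles(quats)) / pl)


# ------------------------------------------------------- motor-control class

def curvature_torsion(
    velocity: np.ndarray,
    acceleration: np.ndarray,
    jerk: np.ndarray,
    speed_eps: float = DEFAULT_SPEED_EPS,
    cross_eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample curvature (1/m) and torsion (1/m) from kinematics.

        kappa = |v x a| / |v|^3
        tau   = ((v x a) . j) / |v x a|^2

    Samples with |v| below ``speed_eps`` or |v x a| below ``cross_eps``
    are flagged invalid rather than raising.
    """
    v = np.atleast_2d(np.asarray(velocity, dtype=float))
    a = np.atleast_2d(np.asarray(acceleration, dtype=float))
    j = np.atleast_2d(np.asarray(jerk, dtype=float))
    cross = np.cross(v, a)
    speed = np.linalg.norm(v, axis=1)
    cross_mag = np.linalg.norm(cross, axis=1)
    valid = (speed > speed_eps) & (cross_mag > cross_eps)
    kappa = np.full(speed.shape, np.nan)
    torsion = np.full(speed.shape, np.nan)
    kappa[valid] = cross_mag[valid] / speed[valid] ** 3
    torsion[valid] = np.einsum("ij,ij->i", cross[valid], j[valid]) / cross_mag[valid] ** 2
    return kappa, torsion, valid


def fit_power_law(
    trial: UniformTrial,
    indices: np.ndarray | None = None,
    torsion_eps: float = DEFAULT_TORSION_EPS,
    speed_eps: float = DEFAULT_SPEED_EPS,
    min_samples: int = 10,
) -> PowerLawFit:
    """OLS regression of log speed on log curvature and log |torsion|.

    Fits ``v = alpha * kappa**beta * |tau|**gamma`` on the samples where
    speed, curvature and torsion are numerically well defined
    (|torsion| >= ``torsion_eps`` keeps the log bounded).  In planar
    scribbling these exponents were proposed to be -1/3 and -1/6.
    """
    if trial.velocity is None or trial.acceleration is None or trial.jerk is None:
        raise ValueError("trial must carry velocity/acceleration/jerk channels")
    sel = slice(None) if indices is None else indices
    kappa, torsion, valid = curvature_torsion(
        trial.velocity[sel], trial.acceleration[sel], trial.jerk[sel], speed_eps
    )
    speed = np.linalg.norm(np.atleast_2d(trial.velocity[sel]), axis=1)
    use = valid & (np.abs(torsion) >= torsion_eps) & (kappa > 0) & (speed > speed_eps)
    n_used = int(np.sum(use))
    if n_used < min_samples:
        raise ValueError(f"only {n_used} valid samples; need >= {min_samples}")
    y = np.log(speed[use])
    design = np.column_stack(
        [np.ones(n_used), np.log(kappa[use]), np.log(np.abs(torsion[use]))]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        alpha=float(np.exp(coef[0])),
        beta=float(coef[1]),
        gamma=float(coef[2]),
        r_squared=float(r2),
        n_used=n_used,
    )


def rms_jerk(seg: SegmentedTrial, segment="bounds") -> float:
    """Duration-normalized root-mean-square jerk, m/s³.

        sqrt( (1 / (t_end - t_start)) * integral |jerk|^2 dt )

    Has units of jerk and is only weakly correlated with completion
    time.  Spans orders of magnitude, so tables report log10 of it.
    """
    if seg.trial.jerk is None:
        raise ValueError("trial must carry a jerk channel")
    idx = _segment_indices(seg, segment)
    t = seg.trial.t[idx]
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("zero duration; RMS jerk undefined")
    jmag2 = np.sum(seg.trial.jerk[idx] ** 2, axis=1)
    return float(np.sqrt(np.trapezoid(jmag2, t) / duration))


# ------------------------------------------------------------ per-trial set

def compute_metric_vector(
    seg: SegmentedTrial,
    geom: TissueGeometry,
    segment="insertion",
    circle_radius: float | None = None,
    plane_method: str = "auto",
    torsion_eps: float = DEFAULT_TORSION_EPS,
) -> MetricVector:
    """All scalar metrics for one trial on one subtask segment.

    Consistency metrics need several repeated trials and are filled in
    at the stage level (see :mod:`needledrive.pipeline`).  Metrics whose
    inputs are unavailable (e.g. exit-point error without a camera
    exit point) come back NaN rather than zero.
    """
    mv = MetricVector(segment=segment if isinstance(segment, str) else segment.name.lower())
    mv.completion_time = completion_time(seg)
    mv.exit_point_error = exit_point_error(geom)
    mv.total_normalized_force = total_normalized_force(seg, geom, segment="bounds")
    mv.max_force = max_force(seg, segment="bounds")
    mv.max_torque_z = max_torque_z(seg, segment="bounds")

    idx = _segment_indices(seg, segment)
    pos = seg.trial.position[idx]
    try:
        mv.path_length = path_length(pos)
    except ValueError:
        mv.path_length = np.nan
    try:
        plane = fit_plane(pos, method=plane_method)
        mv.plane_deviation = plane_deviation(plane, pos)
        circle = fit_circle(pos, plane)
        mv.circle_deviation = circle_deviation(circle, radius=circle_radius)
    except ValueError as err:
        mv.notes["plane_circle"] = str(err)
    try:
        mv.angular_path = angular_path(seg.trial.orientation[idx], mv.path_length)
    except (ValueError, FloatingPointError):
        mv.angular_path = np.nan
    try:
        mv.power_law = fit_power_law(seg.trial, indices=idx, torsion_eps=torsion_eps)
    except ValueError as err:
        mv.notes["power_law"] = str(err)
    try:
        mv.log_jerk = float(np.log10(rms_jerk(seg, segment=segment)))
    except ValueError as err:
        mv.notes["jerk"] = str(err)
    return mv
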