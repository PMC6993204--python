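"""Synthetic needle-driving trials and cohorts.

Real recordings of this task are not publicly deposited, so every
downstream stage is exercised on synthetic data that emulates the
study conditions: arc-shaped insertion trajectories of a needle-driver
tooltip through a planar silicone tissue, the phase-structured
tissue-interaction force pattern (correlated horizontal components and
a mid-insertion vertical sign reversal during insertion, transient
small forces while repositioning, a vertical-dominant extraction), the
subtask structure (insertion, optional corrections, repositioning,
extraction), the two acquisition rates (120 Hz open instrument, 500 Hz
teleoperation), and cohorts of 30 participants x 120 trials split over
three feedback conditions with injectable learning effects.

The exact force waveforms are free parameters of the generator — only
their qualitative phase pattern is constrained — and the silicone
tissue's force-deflection behavior is not modeled; magnitudes are
plausible config values.  Everything is bit-reproducible under a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .trial import SubtaskLabel, TissueGeometry, TrialRecording, UniformTrial

__all__ = [
    "NoiseParams",
    "SyntheticTrialConfig",
    "HelicalScribble",
    "EffectModel",
    "CohortConfig",
    "TrialGroundTruth",
    "default_geometry",
    "generate_ideal_insertion",
    "generate_trial",
    "generate_powerlaw_trajectory",
    "generate_cohort",
    "generate_metric_cohort",
    "CohortDataset",
]

_DRIVING = {"insertion", "correction", "extraction"}
_NON_DRIVING = {"outside", "positioning", "reposition"}


@dataclass(frozen=True)
class NoiseParams:
    """Measurement/behavioral noise amplitudes of the trial generator.

    Defaults are on the order of the magnetic tracker's sub-millimeter
    position noise and the force sensor's noise floor.
    """

    positional_sd: float = 0.0002  # m, isotropic white position noise
    out_of_plane_amplitude: float = 0.0003  # m, slow ripple along plane normal
    radial_drift: float = 0.0005  # m, slow radial wobble around the needle arc
    force_sd: float = 0.005  # N, per-axis force noise

    def __post_init__(self) -> None:
        for name in ("positional_sd", "out_of_plane_amplitude", "radial_drift", "force_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseParams":
        return NoiseParams(
            self.positional_sd * factor,
            self.out_of_plane_amplitude * factor,
            self.radial_drift * factor,
            self.force_sd,
        )


def _default_schedule() -> list[tuple[str, float]]:
    return [
        ("outside", 0.5),
        ("insertion", 3.0),
        ("reposition", 1.0),
        ("extraction", 1.0),
        ("outside", 0.5),
    ]


@dataclass
class SyntheticTrialConfig:
    """Knobs of the single-trial generator.

    ``needle_radius`` defaults to the arc radius of a large semicircular
    suturing needle (~12 mm); it is a config value, not a constant of
    the method.  ``sample_rate`` is the native acquisition rate (120 Hz
    open, 500 Hz teleoperation).
    """

    needle_radius: float = 0.012  # m
    arc_span: float = 2.0  # rad, used by generate_ideal_insertion
    sample_rate: float = 500.0  # Hz
    subtask_schedule: list[tuple[str, float]] = field(default_factory=_default_schedule)
    noise: NoiseParams = field(default_factory=NoiseParams)
    peak_force: float = 2.0  # N
    peak_torque_z: float = 0.01  # N·m
    exit_error_sd: float = 0.002  # m, in-plane actual-exit scatter
    tissue_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tissue_axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.needle_radius <= 0:
            raise ValueError("needle_radius must be positive")
        if any(d <= 0 for _, d in self.subtask_schedule):
            raise ValueError("all schedule durations must be positive")
        labels = [lab for lab, _ in self.subtask_schedule]
        unknown = set(labels) - _DRIVING - _NON_DRIVING
        if unknown:
            raise ValueError(f"unknown schedule labels: {sorted(unknown)}")


def default_geometry(actual_exit: np.ndarray | None = None) -> TissueGeometry:
    """A 10 cm square tissue with a diagonal entrance-exit pair.

    The diagonal orientation mirrors the ideal driving direction of the
    physical task, so horizontal force components are correlated.
    """
    half = 0.05
    contour = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    return TissueGeometry(
        contour=contour,
        entrance_point=np.array([-0.0064, -0.0064, 0.0]),
        desired_exit=np.array([0.0064, 0.0064, 0.0]),
        actual_exit=actual_exit,
    )


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Smooth 0->1 profile with zero endpoint velocity/acceleration."""
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def generate_ideal_insertion(config: SyntheticTrialConfig) -> TrialRecording:
    """A trial whose tooltip path lies exactly on the needle's circle.

    The path sweeps ``arc_span`` radians of a circle of radius
    ``needle_radius`` in the tissue's x-z plane with a minimum-jerk
    angular profile; the tooltip orientation rotates with the arc
    tangent.  Configured noise terms are added on top (zero noise gives
    an exactly planar, exactly circular path).
    """
    if config.arc_span <= 0:
        raise ValueError("arc_span must be positive")
    rng = np.random.default_rng(config.seed)
    duration = sum(d for lab, d in config.subtask_schedule if lab == "insertion") or 3.0
    n = int(round(duration * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate

    ex, ey, ez = config.tissue_axes
    theta = config.arc_span * _minimum_jerk(t / duration)
    radius = config.needle_radius + config.noise.radial_drift * np.sin(2 * np.pi * 0.8 * t)
    center = config.tissue_origin
    position = (
        center
        + radius[:, None] * (np.cos(theta)[:, None] * ex - np.sin(theta)[:, None] * ez)
        + (config.noise.out_of_plane_amplitude * np.sin(2 * np.pi * 1.5 * t))[:, None] * ey
    )
    if config.noise.positional_sd > 0:
        position = position + rng.normal(0, config.noise.positional_sd, position.shape)

    rot = Rotation.from_rotvec(np.outer(theta, ey))
    quats = rot.as_quat()[:, [3, 0, 1, 2]]

    return TrialRecording(
        t=t,
        position=position,
        orientation=quats,
        gripper=np.zeros(n),
        force=np.zeros((n, 3)),
        torque=np.zeros((n, 3)),
        meta={"rate": config.sample_rate, "setup": "synthetic_ideal"},
    )


@dataclass
class TrialGroundTruth:
    """Construction-time truth for a generated trial."""

    intervals: list[tuple[SubtaskLabel, float, float]]  # (label, t0, t1), final labels
    bounds_time: tuple[float, float]  # first/last driving time
    labels: np.ndarray  # per-sample labels at the native rate
    geometry: TissueGeometry  # includes the sampled actual exit point

    def labels_at(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth labels evaluated at arbitrary times."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, int(SubtaskLabel.OUTSIDE))
        for lab, t0, t1 in self.intervals:
            out[(t >= t0) & (t < t1)] = int(lab)
        out[(t < self.bounds_time[0]) | (t > self.bounds_time[1])] = int(SubtaskLabel.OUTSIDE)
        return out


def _validate_schedule(schedule: list[tuple[str, float]]) -> None:
    driving = [lab for lab, _ in schedule if lab in _DRIVING]
    if "insertion" not in driving or "extraction" not in driving:
        raise ValueError("schedule must contain at least insertion and extraction")
    if driving[0] != "insertion" or driving[-1] != "extraction":
        raise ValueError("insertion must be the first and extraction the last driving subtask")
    if driving.count("insertion") != 1 or driving.count("extraction") != 1:
        raise ValueError("schedule must contain exactly one insertion and one extraction")
    prev_driving = False
    for lab, _ in schedule:
        if lab in _DRIVING and prev_driving:
            raise ValueError("driving subtasks must be separated by repositioning")
        prev_driving = lab in _DRIVING


def generate_trial(
    config: SyntheticTrialConfig, geom: TissueGeometry
) -> tuple[TrialRecording, TrialGroundTruth]:
    """Generate one full trial plus its ground-truth segmentation.

    The tooltip enters at the entrance point, follows the needle arc to
    a sampled actual exit point, optionally loops near the entrance for
    corrections, bridges driving subtasks with lifted repositioning
    moves, and extracts near the exit.  Forces follow the qualitative
    phase pattern of the task; outside driving subtasks the force
    magnitude stays below the 0.06 N noise threshold by construction.
    """
    _validate_schedule(config.subtask_schedule)
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    total = sum(d for _, d in config.subtask_schedule)
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    # geometry with a per-trial actual exit point
    ez = geom.frame_axes[2]
    e1, e2 = geom.frame_axes[0], geom.frame_axes[1]
    radius = config.needle_radius
    entrance = geom.entrance_point
    if np.linalg.norm(geom.desired_exit - entrance) >= 2 * radius:
        raise ValueError("desired entrance-exit distance exceeds the needle diameter")
    err = rng.normal(0, config.exit_error_sd, 2)
    actual_exit = geom.desired_exit + err[0] * e1 + err[1] * e2
    chord = actual_exit - entrance
    d = float(np.linalg.norm(chord))
    # the needle cannot exit farther than its own diameter from the
    # entrance; clamp rare extreme exit-error draws onto that reach
    if d >= 1.96 * radius:
        actual_exit = entrance + chord * (1.96 * radius / d)
        chord = actual_exit - entrance
        d = float(np.linalg.norm(chord))
    geom = replace(geom, actual_exit=actual_exit)
    x_c = chord / d
    y_c = np.cross(ez, x_c)
    y_c /= np.linalg.norm(y_c)
    h = math.sqrt(radius**2 - (d / 2) ** 2)
    center = (entrance + actual_exit) / 2 + h * ez
    phi_entrance = math.atan2(h, -d / 2)
    phi_exit = math.atan2(h, d / 2)
    span = phi_entrance - phi_exit

    def arc_point(phi: np.ndarray) -> np.ndarray:
        return center + radius * (np.cos(phi)[:, None] * x_c - np.sin(phi)[:, None] * ez)

    # schedule boundaries
    entries = []
    t0 = 0.0
    for lab, dur in config.subtask_schedule:
        entries.append([lab, t0, t0 + dur])
        t0 += dur

    position = np.zeros((n, 3))
    force = np.zeros((n, 3))
    torque = np.zeros((n, 3))
    gripper = np.ones(n)
    rotangle = np.zeros(n)

    # anchor points of driving subtasks for repositioning bridges
    anchors = {}
    for k, (lab, a, b) in enumerate(entries):
        if lab == "insertion":
            anchors[k] = (entrance.copy(), actual_exit.copy())
        elif lab == "correction":
            c0 = entrance + 0.003 * x_c - 0.002 * ez
            anchors[k] = (c0, c0)
        elif lab == "extraction":
            top = actual_exit + 0.004 * x_c + 0.010 * ez
            anchors[k] = (actual_exit.copy(), top)

    def neighbor_anchor(k: int, direction: int) -> np.ndarray | None:
        j = k + direction
        while 0 <= j < len(entries):
            if j in anchors:
                return anchors[j][0 if direction > 0 else 1]
            j += direction
        return None

    env_floor = 0.25  # envelope floor keeps driving force above the noise threshold

    for k, (lab, a, b) in enumerate(entries):
        idx = np.flatnonzero((t >= a - 1e-12) & (t < b - 1e-12))
        if k == len(entries) - 1:
            idx = np.flatnonzero(t >= a - 1e-12)
        if idx.size == 0:
            continue
        p = (t[idx] - a) / (b - a)
        smooth = _minimum_jerk(p)
        env = config.peak_force * (env_floor + (1 - env_floor) * np.sin(np.pi * p))

        if lab == "insertion":
            phi = phi_entrance - span * smooth
            position[idx] = arc_point(phi)
            rotangle[idx] = span * smooth
            gripper[idx] = 0.0
            # correlated horizontal push along the chord; vertical sign
            # reversal halfway through the throw
            horiz = x_c - (x_c @ ez) * ez
            horiz /= np.linalg.norm(horiz)
            force[idx] = np.outer(0.55 * env, horiz) - np.outer(
                0.8 * env * np.cos(np.pi * p), ez
            )
            torque[idx, 2] = config.peak_torque_z * np.sin(np.pi * p)
        elif lab == "correction":
            c0, _ = anchors[k]
            ang = 2 * np.pi * smooth
            position[idx] = (
                c0
                + 0.003 * (np.cos(ang)[:, None] - 1) * x_c
                + 0.003 * np.sin(ang)[:, None] * y_c
            )
            rotangle[idx] = rotangle[idx - 1][0] if idx[0] > 0 else 0.0
            gripper[idx] = 0.0
            force[idx] = np.outer(0.5 * env, x_c) + np.outer(0.5 * env, ez)
        elif lab == "extraction":
            start, top = anchors[k]
            position[idx] = start + smooth[:, None] * (top - start)
            rotangle[idx] = span
            gripper[idx] = 0.0
            force[idx] = np.outer(0.85 * env, ez) + np.outer(
                0.3 * env * (1 - p), x_c
            )
        else:  # outside / positioning / reposition bridges
            start = neighbor_anchor(k, -1)
            stop = neighbor_anchor(k, +1)
            if start is None and stop is None:
                start = stop = geom.frame_origin + 0.02 * ez
            elif start is None:
                start = stop + 0.02 * ez
            elif stop is None:
                stop = start + 0.02 * ez
            lift = 0.006 * np.sin(np.pi * p)
            position[idx] = start + smooth[:, None] * (stop - start) + lift[:, None] * ez
            prev = np.flatnonzero(t < a - 1e-12)
            rotangle[idx] = rotangle[prev[-1]] if prev.size else 0.0
            gripper[idx] = 1.0

    # carry rotation angle forward through non-driving gaps
    for i in range(1, n):
        if gripper[i] == 1.0:
            rotangle[i] = rotangle[i - 1]

    # noise
    noise = config.noise
    if noise.positional_sd > 0:
        position += rng.normal(0, noise.positional_sd, position.shape)
    if noise.out_of_plane_amplitude > 0:
        position += (noise.out_of_plane_amplitude * np.sin(2 * np.pi * 1.5 * t))[:, None] * y_c
    if noise.force_sd > 0:
        force += rng.normal(0, noise.force_sd, force.shape)
        torque += rng.normal(0, noise.force_sd * 0.02, torque.shape)

    # by construction: outside driving subtasks the force stays under threshold
    driving_mask = np.zeros(n, dtype=bool)
    for lab, a, b in entries:
        if lab in _DRIVING:
            sel = (t >= a - 1e-12) & (t < b - 1e-12)
            driving_mask |= sel
    out_mag = np.linalg.norm(force[~driving_mask], axis=1)
    too_big = out_mag > 0.05
    if np.any(too_big):
        scale = np.ones_like(out_mag)
        scale[too_big] = 0.05 / out_mag[too_big]
        force[~driving_mask] *= scale[:, None]

    quats = Rotation.from_rotvec(np.outer(rotangle, y_c)).as_quat()[:, [3, 0, 1, 2]]

    trial = TrialRecording(
        t=t,
        position=position,
        orientation=quats,
        gripper=gripper,
        force=force,
        torque=torque,
        meta={"rate": fs, "setup": "teleop" if fs >= 250 else "open"},
    )

    # ground truth: scheduled labels, OUTSIDE outside the driving bounds,
    # REPOSITION in gaps between driving runs
    drive_times = t[driving_mask]
    bounds_time = (float(drive_times[0]), float(drive_times[-1]))
    label_map = {
        "insertion": SubtaskLabel.INSERTION,
        "correction": SubtaskLabel.CORRECTION,
        "extraction": SubtaskLabel.EXTRACTION,
        "reposition": SubtaskLabel.REPOSITION,
        "outside": SubtaskLabel.OUTSIDE,
        "positioning": SubtaskLabel.OUTSIDE,
    }
    intervals = []
    for lab, a, b in entries:
        final = label_map[lab]
        if final is SubtaskLabel.OUTSIDE and bounds_time[0] < a and b < bounds_time[1] + 1e-12:
            final = SubtaskLabel.REPOSITION  # inside the trial, gaps are repositioning
        intervals.append((final, a, b))
    gt = TrialGroundTruth(
        intervals=intervals,
        bounds_time=bounds_time,
        labels=np.zeros(n, dtype=int),
        geometry=geom,
    )
    gt.labels = gt.labels_at(t)
    return trial, gt


# ------------------------------------------------------ power-law trajectory

@dataclass(frozen=True)
class HelicalScribble:
    """Analytic 3D base curve with nonvanishing curvature and torsion.

    An elliptic helix with a superimposed axial ripple::

        c(u) = (A cos u, B sin u, C u + D sin(k u))

    Parametric derivatives are closed-form, so curvature and torsion
    along the curve are exact.
    """

    a: float = 0.04
    b: float = 0.03
    c: float = 0.012
    d: float = 0.001
    k: int = 2
    u_start: float = 0.0
    u_end: float = 4 * math.pi

    def point(self, u: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.a * np.cos(u), self.b * np.sin(u), self.c * u + self.d * np.sin(self.k * u)]
        )

    def d1(self, u: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [-self.a * np.sin(u), self.b * np.cos(u), self.c + self.d * self.k * np.cos(self.k * u)]
        )

    def d2(self, u: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [-self.a * np.cos(u), -self.b * np.sin(u), -self.d * self.k**2 * np.sin(self.k * u)]
        )

    def d3(self, u: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.a * np.sin(u), -self.b * np.cos(u), -self.d * self.k**3 * np.cos(self.k * u)]
        )


def generate_powerlaw_trajectory(
    alpha: float,
    beta: float,
    gamma: float,
    base_path: HelicalScribble | None = None,
    sample_rate: float = 100.0,
    n_dense: int = 20001,
) -> UniformTrial:
    """Time-reparameterize a 3D curve so speed obeys the power law.

    The base curve is traversed with speed
    ``v(u) = alpha * kappa(u)**beta * |tau(u)|**gamma`` computed from
    the curve's exact curvature/torsion; velocity, acceleration and
    jerk channels are derived by the chain rule, so the sampled
    kinematics satisfy the law to numerical precision.

    Raises
    ------
    ValueError
        If curvature or torsion (nearly) vanishes anywhere on the span.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    path = base_path if base_path is not None else HelicalScribble()
    u = np.linspace(path.u_start, path.u_end, n_dense)
    c1, c2, c3 = path.d1(u), path.d2(u), path.d3(u)
    cross = np.cross(c1, c2)
    speed1 = np.linalg.norm(c1, axis=1)
    cross_mag = np.linalg.norm(cross, axis=1)
    kappa = cross_mag / speed1**3
    torsion = np.einsum("ij,ij->i", cross, c3) / cross_mag**2
    if np.min(kappa) < 1e-9 or np.min(np.abs(torsion)) < 1e-9:
        raise ValueError("base path has (near-)vanishing curvature or torsion")

    v = alpha * kappa**beta * np.abs(torsion) ** gamma
    g = v / speed1  # du/dt along the curve
    g_spline = CubicSpline(u, g)
    t_dense = cumulative_trapezoid(1.0 / g, u, initial=0.0)
    duration = t_dense[-1]
    n = int(np.floor(duration * sample_rate)) + 1
    t_k = np.arange(n) / sample_rate
    u_k = CubicSpline(t_dense, u)(t_k)

    g0 = g_spline(u_k)
    g1 = g_spline(u_k, 1)
    g2 = g_spline(u_k, 2)
    du = g0
    ddu = g1 * g0
    dddu = (g2 * g0 + g1**2) * g0

    c1k, c2k, c3k = path.d1(u_k), path.d2(u_k), path.d3(u_k)
    position = path.point(u_k)
    velocity = c1k * du[:, None]
    acceleration = c2k * du[:, None] ** 2 + c1k * ddu[:, None]
    jerk = (
        c3k * du[:, None] ** 3
        + 3 * c2k * (du * ddu)[:, None]
        + c1k * dddu[:, None]
    )

    quats = np.zeros((n, 4))
    quats[:, 0] = 1.0
    return UniformTrial(
        t=t_k,
        position=position,
        orientation=quats,
        gripper=np.zeros(n),
        force=np.zeros((n, 3)),
        torque=np.zeros((n, 3)),
        meta={"rate": sample_rate, "setup": "synthetic_powerlaw"},
        rate=sample_rate,
        velocity=velocity,
        acceleration=acceleration,
        jerk=jerk,
    )


# ------------------------------------------------------------------ cohorts

LOG_METRICS = (
    "completion_time",
    "exit_point_error",
    "total_normalized_force",
    "max_force",
    "max_torque_z",
    "force_consistency",
    "path_length",
    "circle_deviation",
    "plane_deviation",
    "angular_path",
    "trajectory_consistency",
    "powerlaw_alpha",
)
LINEAR_METRICS = ("powerlaw_beta", "powerlaw_gamma", "log_jerk")

# plausible open-setup baseline magnitudes, chosen once at realistic scales
_BASELINES = {
    "completion_time": 5.0,  # s
    "exit_point_error": 0.003,  # m (teleop only)
    "total_normalized_force": 30.0,  # N·s/m (teleop only)
    "max_force": 2.5,  # N
    "max_torque_z": 0.010,  # N·m
    "force_consistency": 500.0,  # N²
    "path_length": 0.06,  # m
    "circle_deviation": 5e-6,  # m·rad
    "plane_deviation": 5e-6,  # m²
    "angular_path": 30.0,  # rad/m
    "trajectory_consistency": 0.01,  # m²
    "powerlaw_alpha": 0.05,
    "powerlaw_beta": -0.30,
    "powerlaw_gamma": -0.14,
    "log_jerk": 1.5,  # log10(m/s³)
}
_LINEAR_TRIAL_SD = {"powerlaw_beta": 0.04, "powerlaw_gamma": 0.03, "log_jerk": 0.25}


def _default_learning() -> dict[str, float]:
    # log-scale reductions over the teleoperation phase
    return {
        "completion_time": 0.45,
        "total_normalized_force": 0.35,
        "force_consistency": 0.60,
        "trajectory_consistency": 0.50,
    }


def _default_tele_offset() -> dict[str, float]:
    # teleoperation is initially slower and less consistent than open
    return {
        "completion_time": 0.60,
        "force_consistency": 0.50,
        "trajectory_consistency": 0.40,
        "log_jerk": -1.0,
    }


@dataclass
class EffectModel:
    """Learning effects injected into cohort generation.

    ``learning`` maps metric names to additive effects on the log scale
    (linear scale for the three non-positive metrics) accrued linearly
    across the teleoperation phase: positive values mean the metric
    decreases with practice.  Log-scale effects keep strictly positive
    metrics positive.  ``participant_sd`` is the between-participant
    spread of baselines; ``trial_sd`` the within-participant trial
    noise (both log-scale for positive metrics).
    """

    learning: dict[str, float] = field(default_factory=_default_learning)
    tele_offset: dict[str, float] = field(default_factory=_default_tele_offset)
    participant_sd: float = 0.25
    trial_sd: float = 0.35

    @classmethod
    def null(cls) -> "EffectModel":
        """No learning anywhere (for calibration of false positives)."""
        return cls(learning={}, tele_offset=_default_tele_offset())


def _default_blocks() -> dict[str, int]:
    return {"open1": 4, "tele": 6, "open2": 2}


@dataclass
class CohortConfig:
    """Cohort layout: 3 feedback groups x participants x 120 trials.

    The default phase structure is 4 open blocks, 6 teleoperation
    blocks and 2 more open blocks of 10 trials each (120 trials per
    participant).  Custom block structures are allowed for small
    end-to-end runs but every phase must keep at least 5 trials, the
    stage-selector width.
    """

    n_per_group: int = 10
    conditions: tuple[str, ...] = ("NF", "PE", "DF")
    trials_per_block: int = 10
    blocks: dict[str, int] = field(default_factory=_default_blocks)
    effect_model: EffectModel = field(default_factory=EffectModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (contrasts undefined otherwise)")
        for phase in ("open1", "tele", "open2"):
            if phase not in self.blocks:
                raise ValueError(f"blocks must define phase {phase!r}")
            if self.blocks[phase] * self.trials_per_block < 5:
                raise ValueError(f"phase {phase!r} must contain at least 5 trials")

    @property
    def trials_per_participant(self) -> int:
        return self.trials_per_block * sum(self.blocks.values())

    def phase_of(self, trial_index: int) -> tuple[str, int, int]:
        """(phase, block index, trial-within-phase) for a global index."""
        tpb = self.trials_per_block
        block = trial_index // tpb
        edges = {}
        start = 0
        for phase in ("open1", "tele", "open2"):
            edges[phase] = (start, start + self.blocks[phase])
            start += self.blocks[phase]
        for phase, (b0, b1) in edges.items():
            if b0 <= block < b1:
                return phase, block, trial_index - b0 * tpb
        raise IndexError(trial_index)


@dataclass
class CohortDataset:
    """Manifest plus generated trials of a signal-level cohort."""

    manifest: pd.DataFrame
    trials: dict[tuple[str, int], tuple[TrialRecording, TrialGroundTruth]]
    config: CohortConfig


def generate_metric_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Per-trial metric values drawn directly from the effect model.

    One row per (participant, trial) with condition/phase/block
    annotations and one column per metric.  Positive metrics are
    log-normal around participant baselines with the configured
    teleoperation offset and a learning drift accrued linearly over the
    teleoperation phase; exit-point error and total normalized force
    are NaN in the open phases (no camera exit point there).
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    em = cfg.effect_model
    n_tele = cfg.blocks["tele"] * cfg.trials_per_block
    rows = []
    pid = 0
    for cond in cfg.conditions:
        for _ in range(cfg.n_per_group):
            participant = f"P{pid:02d}"
            pid += 1
            base_log = {
                m: rng.normal(0, em.participant_sd) for m in LOG_METRICS
            }
            base_lin = {
                m: rng.normal(0, em.participant_sd * _LINEAR_TRIAL_SD[m] / 0.35)
                for m in LINEAR_METRICS
            }
            for trial in range(cfg.trials_per_participant):
                phase, block, t_in_phase = cfg.phase_of(trial)
                is_tele = phase == "tele"
                progress = (t_in_phase / max(n_tele - 1, 1)) if is_tele else 0.0
                row = {
                    "participant": participant,
                    "condition": cond,
                    "phase": phase,
                    "block": block,
                    "trial": trial,
                    "trial_in_phase": t_in_phase,
                    "setup": "teleop" if is_tele else "open",
                }
                for m in LOG_METRICS:
                    if m in ("exit_point_error", "total_normalized_force") and not is_tele:
                        row[m] = np.nan
                        continue
                    mu = math.log(_BASELINES[m]) + base_log[m]
                    if is_tele:
                        mu += em.tele_offset.get(m, 0.0)
                        mu -= em.learning.get(m, 0.0) * progress
                    row[m] = math.exp(mu + rng.normal(0, em.trial_sd))
                for m in LINEAR_METRICS:
                    mu = _BASELINES[m] + base_lin[m]
                    if is_tele:
                        mu += em.tele_offset.get(m, 0.0)
                        mu -= em.learning.get(m, 0.0) * progress
                    row[m] = mu + rng.normal(0, _LINEAR_TRIAL_SD[m])
                rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    cfg: CohortConfig,
    level: str = "signal",
    base_trial: SyntheticTrialConfig | None = None,
    geometry: TissueGeometry | None = None,
):
    """Generate a cohort at either fidelity tier.

    ``level="signal"`` synthesizes full 6-DOF trials (use small
    configs); ``level="metrics"`` draws per-trial metric values from
    the same effect model and returns a tidy DataFrame (cheap, for
    statistical calibration at scale).
    """
    if level == "metrics":
        return generate_metric_cohort(cfg)
    if level != "signal":
        raise ValueError(f"unknown level {level!r}")

    base = base_trial if base_trial is not None else SyntheticTrialConfig()
    geom = geometry if geometry is not None else default_geometry()
    em = cfg.effect_model
    rng = np.random.default_rng(cfg.seed)
    n_tele = cfg.blocks["tele"] * cfg.trials_per_block

    manifest_rows = []
    trials: dict[tuple[str, int], tuple[TrialRecording, TrialGroundTruth]] = {}
    pid = 0
    for cond in cfg.conditions:
        for _ in range(cfg.n_per_group):
            participant = f"P{pid:02d}"
            pid += 1
            p_tempo = rng.normal(0, em.participant_sd)
            for trial_idx in range(cfg.trials_per_participant):
                phase, block, t_in_phase = cfg.phase_of(trial_idx)
                is_tele = phase == "tele"
                progress = (t_in_phase / max(n_tele - 1, 1)) if is_tele else 0.0
                log_tempo = p_tempo + rng.normal(0, em.trial_sd * 0.3)
                if is_tele:
                    log_tempo += em.tele_offset.get("completion_time", 0.0)
                    log_tempo -= em.learning.get("completion_time", 0.0) * progress
                tempo = math.exp(log_tempo)
                noise_factor = math.exp(
                    -em.learning.get("trajectory_consistency", 0.0) * progress * 0.5
                )
                schedule = [
                    (lab, dur * tempo if lab in _DRIVING or lab == "reposition" else dur)
                    for lab, dur in base.subtask_schedule
                ]
                tcfg = replace(
                    base,
                    subtask_schedule=schedule,
                    sample_rate=500.0 if is_tele else 120.0,
                    noise=base.noise.scaled(noise_factor),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                trial, gt = generate_trial(tcfg, geom)
                trial.meta.update(
                    participant=participant,
                    condition=cond,
                    phase=phase,
                    block=block,
                    trial=trial_idx,
                    trial_in_phase=t_in_phase,
                    setup="teleop" if is_tele else "open",
                )
                if not is_tele:
                    # no camera exit point in the open setup
                    gt.geometry = replace(gt.geometry, actual_exit=None)
                key = (participant, trial_idx)
                trials[key] = (trial, gt)
                manifest_rows.append(
                    {
                        "participant": participant,
                        "condition": cond,
                        "phase": phase,
                        "block": block,
                        "trial": trial_idx,
                        "trial_in_phase": t_in_phase,
                        "setup": "teleop" if is_tele else "open",
                    }
                )
    return CohortDataset(manifest=pd.DataFrame(manifest_rows), trials=trials, config=cfg)
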