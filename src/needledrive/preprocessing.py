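"""Resampling, zero-phase filtering, and the derivative chain.

Raw recordings arrive at the native rate of each apparatus (120 Hz for
the open-instrument magnetic tracker, 500 Hz for the teleoperation
robot).  All channels are brought to a common uniform grid (100 Hz by
default): position, force and torque by shape-preserving piecewise
cubic (monotone Hermite / PCHIP) interpolation, orientation by
per-interval spherical linear interpolation with sign continuity, and
the categorical gripper channel by nearest-previous sample.  The
position channel is then low-pass filtered with a zero-phase 2nd-order
Butterworth (10 Hz design cutoff; the forward-backward double pass
moves the empirical -3 dB point to 8 Hz), and velocity, acceleration
and jerk are obtained by central differencing with the same filter
re-applied after every differentiation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation, Slerp

from .trial import TrialRecording, UniformTrial

__all__ = [
    "resample_to_uniform",
    "zero_phase_lowpass",
    "derivative_chain",
    "preprocess_trial",
]

DEFAULT_RATE = 100.0
DEFAULT_CUTOFF = 10.0
DEFAULT_ORDER = 2


def _enforce_sign_continuity(quats: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive dot products are >= 0.

    Unit quaternions double-cover rotations; without this, interpolation
    can take the long way around and inflate angular-path measures.
    """
    q = quats.copy()
    dots = np.einsum("ij,ij->i", q[:-1], q[1:])
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def resample_to_uniform(trial: TrialRecording, target_rate: float = DEFAULT_RATE) -> TrialRecording:
    """Resample all channels of a trial onto a uniform grid.

    The new grid starts at the first original timestamp and spans only
    the original time support (no extrapolation).

    Raises
    ------
    ValueError
        If the trial has fewer than 4 samples or duplicate timestamps.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t = trial.t
    if len(t) < 4:
        raise ValueError("resampling requires at least 4 samples")
    dts = np.diff(t)
    if np.any(dts == 0):
        raise ValueError("duplicate timestamps in trial")
    if np.any(dts < 0):
        raise ValueError("timestamps must be monotone increasing")

    dt = 1.0 / target_rate
    n_new = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    t_new = t[0] + dt * np.arange(n_new)
    t_new[-1] = min(t_new[-1], t[-1])  # guard float overshoot of the support

    def pchip(y: np.ndarray) -> np.ndarray:
        return PchipInterpolator(t, y, axis=0)(t_new)

    position = pchip(trial.position)
    force = pchip(trial.force)
    torque = pchip(trial.torque)

    # orientation: sign-continuous per-interval slerp
    q = _enforce_sign_continuity(trial.orientation)
    rot = Rotation.from_quat(q[:, [1, 2, 3, 0]])  # to scalar-last
    q_new = Slerp(t, rot)(t_new).as_quat()[:, [3, 0, 1, 2]]  # back to scalar-first
    q_new /= np.linalg.norm(q_new, axis=1)[:, None]
    q_new = _enforce_sign_continuity(q_new)

    # gripper: categorical -> nearest-previous (zero-order hold)
    idx = np.searchsorted(t, t_new + 1e-12, side="right") - 1
    gripper = trial.gripper[np.clip(idx, 0, len(t) - 1)]

    meta = dict(trial.meta)
    meta["rate"] = target_rate
    return TrialRecording(
        t=t_new,
        position=position,
        orientation=q_new,
        gripper=gripper,
        force=force,
        torque=torque,
        meta=meta,
    )


def zero_phase_lowpass(
    series: np.ndarray,
    fs: float,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass filter (zero phase lag).

    The filter is designed at ``cutoff`` (single-pass -3 dB point); the
    double pass squares the magnitude response, so the effective -3 dB
    point is lower (8 Hz for the default 10 Hz / order-2 design at
    100 Hz sampling).  Edge transients are suppressed with reflective
    padding of three times the filter order.

    Parameters
    ----------
    series : (N,) or (N, d) uniformly sampled signal.
    fs : sampling rate, Hz.
    """
    series = np.asarray(series, dtype=float)
    padlen = 3 * order
    if series.shape[0] <= padlen:
        raise ValueError(
            f"series of length {series.shape[0]} too short for edge padding {padlen}"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    return signal.filtfilt(b, a, series, axis=0, padtype="even", padlen=padlen)


def derivative_chain(
    trial: TrialRecording,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_ORDER,
) -> UniformTrial:
    """Differentiate position to velocity, acceleration and jerk.

    Assumes the trial is uniformly sampled and its position channel
    already filtered.  Uses central differences (one-sided at the
    edges); each derivative is re-filtered with the same zero-phase
    low-pass before the next differentiation, mirroring the measurement
    chain used for the raw position.  Interior samples are exact for
    polynomials up to the differencing order; the first/last few
    samples carry edge transients.
    """
    rate = float(trial.meta.get("rate", DEFAULT_RATE))
    dt = 1.0 / rate

    def ddt(y: np.ndarray) -> np.ndarray:
        d = np.gradient(y, dt, axis=0)
        return zero_phase_lowpass(d, fs=rate, cutoff=cutoff, order=order)

    velocity = ddt(trial.position)
    acceleration = ddt(velocity)
    jerk = ddt(acceleration)
    return UniformTrial(
        t=trial.t,
        position=trial.position,
        orientation=trial.orientation,
        gripper=trial.gripper,
        force=trial.force,
        torque=trial.torque,
        meta=dict(trial.meta),
        rate=rate,
        velocity=velocity,
        acceleration=acceleration,
        jerk=jerk,
    )


def preprocess_trial(
    trial: TrialRecording,
    target_rate: float = DEFAULT_RATE,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_ORDER,
) -> UniformTrial:
    """Full preprocessing: resample, filter position, differentiate."""
    uniform = resample_to_uniform(trial, target_rate)
    uniform.position = zero_phase_lowpass(
        uniform.position, fs=target_rate, cutoff=cutoff, order=order
    )
    return derivative_chain(uniform, cutoff=cutoff, order=order)
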