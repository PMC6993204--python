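"""Teleoperation force-feedback models.

Two haptic-feedback laws are modeled.  Position-exchange (PE) feedback
renders a force proportional to the pose error between the desired
(master-commanded) and current patient-side tooltip state through a PD
controller::

    f = K_P (x_des - x_cur) + K_D (v_des - v_cur)

with positional gain ``K_P`` in N/m and derivative gain ``K_D`` in
N·s/m.  Direct feedback (DF) transmits the force-sensor reading scaled
by a dimensionless gain ``G_DF``::

    f = G_DF * f_sensed

Both are linear maps; PE reduces to a pure stiffness when the velocity
error vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeedbackParams", "pe_feedback_force", "df_feedback_force"]


@dataclass(frozen=True)
class FeedbackParams:
    """Gains and thresholds of the teleoperation feedback loop.

    Attributes
    ----------
    k_p : positional stiffness gain, N/m.
    k_d : damping gain, N·s/m.
    g_df : direct-feedback scalar gain (0 < g_df <= 1).
    s_tele : master-to-patient translation scaling (0 < s_tele <= 1).
    force_noise_threshold : force-sensor noise floor, N; samples below
        it are treated as no tissue contact.
    """

    k_p: float = 1000.0
    k_d: float = 30.0
    g_df: float = 0.7
    s_tele: float = 0.4
    force_noise_threshold: float = 0.06

    def __post_init__(self) -> None:
        if self.k_p < 0 or self.k_d < 0:
            raise ValueError("gains must be nonnegative")
        if not 0 < self.g_df <= 1:
            raise ValueError("g_df must be in (0, 1]")
        if not 0 < self.s_tele <= 1:
            raise ValueError("s_tele must be in (0, 1]")
        if self.force_noise_threshold < 0:
            raise ValueError("force_noise_threshold must be nonnegative")


def _as_finite_vec3(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pe_feedback_force(
    x_des, x_cur, v_des, v_cur, params: FeedbackParams = FeedbackParams()
) -> np.ndarray:
    """Position-exchange PD feedback force.

    All inputs are 3-vectors in a common Cartesian frame (positions in
    m, velocities in m/s); returns the rendered force in N.
    """
    x_des = _as_finite_vec3(x_des, "x_des")
    x_cur = _as_finite_vec3(x_cur, "x_cur")
    v_des = _as_finite_vec3(v_des, "v_des")
    v_cur = _as_finite_vec3(v_cur, "v_cur")
    return params.k_p * (x_des - x_cur) + params.k_d * (v_des - v_cur)


def df_feedback_force(f_sensed, params: FeedbackParams = FeedbackParams()) -> np.ndarray:
    """Direct feedback: force-sensor reading scaled by ``g_df``."""
    f_sensed = _as_finite_vec3(f_sensed, "f_sensed")
    return params.g_df * f_sensed
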