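import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import needledrive.metrics as M
from needledrive.synthetic import NoiseParams, SyntheticTrialConfig, generate_ideal_insertion
from needledrive.trial import TissueGeometry

from conftest import make_uniform_trial, whole_trial_segment


def square_geometry(actual_exit=None, entrance=(-0.01, 0, 0), desired=(0.01, 0, 0)):
    half = 0.05
    contour = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    return TissueGeometry(
        contour=contour,
        entrance_point=np.array(entrance, dtype=float),
        desired_exit=np.array(desired, dtype=float),
        actual_exit=None if actual_exit is None else np.array(actual_exit, dtype=float),
    )


class TestTaskMetrics:
    def test_completion_time_is_stage_difference(self):
        t = np.arange(0, 6, 0.01)
        trial = make_uniform_trial(t, np.zeros((len(t), 3)))
        seg = whole_trial_segment(trial)
        seg.bounds = (120, 520)
        assert M.completion_time(seg) == pytest.approx(4.0, abs=1e-12)

    def test_degenerate_single_sample_trial_has_zero_time(self):
        t = np.arange(0, 1, 0.01)
        trial = make_uniform_trial(t, np.zeros((len(t), 3)))
        seg = whole_trial_segment(trial)
        seg.bounds = (40, 40)
        assert M.completion_time(seg) == 0.0

    def test_exit_error_three_four_five(self):
        geom = square_geometry(actual_exit=(0.013, 0.004, 0.0), desired=(0.01, 0.0, 0.0))
        assert M.exit_point_error(geom) == pytest.approx(0.005, rel=1e-12)

    def test_exit_error_zero_for_identical_points(self):
        geom = square_geometry(actual_exit=(0.01, 0.0, 0.0))
        assert M.exit_point_error(geom) == 0.0

    def test_exit_error_random_pairs_match_independent_distance(self, rng):
        for _ in range(20):
            d, a = rng.uniform(-0.02, 0.02, (2, 2))
            geom = square_geometry(actual_exit=(a[0], a[1], 0.0), desired=(d[0], d[1], 0.0))
            oracle = np.sqrt((d[0] - a[0]) ** 2 + (d[1] - a[1]) ** 2)
            assert M.exit_point_error(geom) == pytest.approx(oracle, abs=1e-15)

    def test_exit_error_unavailable_without_actual_exit(self):
        assert np.isnan(M.exit_point_error(square_geometry()))


class TestForceMetrics:
    @staticmethod
    def force_trial(fmag, dt=0.01):
        n = len(fmag)
        t = np.arange(n) * dt
        force = np.zeros((n, 3))
        force[:, 0] = fmag
        trial = make_uniform_trial(t, np.zeros((n, 3)), force=force)
        return whole_trial_segment(trial)

    def test_constant_force_integral(self):
        seg = self.force_trial(np.ones(201))  # 1 N for 2 s
        geom = square_geometry(actual_exit=(0.01, 0, 0), entrance=(-0.01, 0, 0))
        assert geom.d_ie == pytest.approx(0.02)
        assert M.total_normalized_force(seg, geom) == pytest.approx(100.0, rel=1e-12)

    def test_zero_force_gives_zero(self):
        seg = self.force_trial(np.zeros(101))
        geom = square_geometry(actual_exit=(0.01, 0, 0))
        assert M.total_normalized_force(seg, geom) == 0.0

    def test_ramp_matches_closed_form_integral(self):
        # f(t) = 3t over 2 s: integral = 3 * 2^2 / 2 = 6 N·s exactly
        t = np.arange(0, 2.005, 0.01)
        seg = self.force_trial(3 * t)
        geom = square_geometry(actual_exit=(0.01, 0, 0))
        d_ie = 0.02
        expected = 3 * t[-1] ** 2 / 2 / d_ie
        assert M.total_normalized_force(seg, geom) == pytest.approx(expected, abs=1e-9)

    def test_coincident_entrance_exit_is_error(self):
        seg = self.force_trial(np.ones(51))
        geom = square_geometry(actual_exit=(-0.01, 0, 0))  # equals entrance
        with pytest.raises(ValueError, match="d_ie"):
            M.total_normalized_force(seg, geom)

    def test_max_force_finds_inserted_peak(self):
        fmag = np.abs(np.sin(np.linspace(0, 3, 400)))
        fmag[217] = 3.0
        seg = self.force_trial(fmag)
        assert M.max_force(seg) == pytest.approx(3.0)

    def test_max_torque_zero_trace(self):
        seg = self.force_trial(np.zeros(100))
        assert M.max_torque_z(seg) == 0.0

    def test_max_torque_uses_absolute_value(self, rng):
        n = 300
        seg = self.force_trial(np.zeros(n))
        seg.trial.torque[:, 2] = rng.normal(0, 0.01, n)
        seg.trial.torque[100, 2] = -0.5
        oracle = max(abs(v) for v in seg.trial.torque[:, 2])  # exhaustive scan
        assert M.max_torque_z(seg) == pytest.approx(oracle, abs=1e-15)

    def test_max_force_matches_exhaustive_scan(self, rng):
        n = 250
        seg = self.force_trial(np.zeros(n))
        seg.trial.force = rng.normal(0, 1, (n, 3))
        oracle = max(np.sqrt(fx**2 + fy**2 + fz**2) for fx, fy, fz in seg.trial.force)
        assert M.max_force(seg) == pytest.approx(oracle, abs=1e-12)


class TestPathLengthProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    point = st.tuples(
        st.floats(-1, 1, allow_nan=False), st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pts=st.lists(point, min_size=2, max_size=20))
    def test_dominates_endpoint_distance_and_is_nonnegative(self, pts):
        path = np.array(pts)
        pl = M.path_length(path)
        assert pl >= 0
        assert pl >= np.linalg.norm(path[-1] - path[0]) - 1e-12


class TestPathLength:
    def test_straight_segment(self):
        path = np.linspace([0, 0, 0], [0.1, 0, 0], 50)
        assert M.path_length(path) == pytest.approx(0.1, abs=1e-12)

    def test_dense_semicircle_approaches_pi_r(self):
        r = 0.02
        theta = np.linspace(0, np.pi, 5000)
        path = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)])
        assert M.path_length(path) == pytest.approx(np.pi * r, rel=1e-6)

    def test_at_least_endpoint_distance(self, rng):
        path = rng.normal(0, 0.01, (100, 3)).cumsum(axis=0)
        assert M.path_length(path) >= np.linalg.norm(path[-1] - path[0]) - 1e-15


class TestPlaneAndCircleFits:
    @staticmethod
    def tilted_circle(radius=0.0187, n=200, tilt=0.3, noise=0.0, rng=None,
                      arc=2 * np.pi):
        theta = np.linspace(0, arc, n)
        pts = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
        )
        if noise and rng is not None:
            pts[:, :2] += rng.normal(0, noise, (n, 2))
        rot = Rotation.from_rotvec([tilt, 0.1, 0.0])
        return pts @ rot.as_matrix().T + np.array([0.01, -0.02, 0.005])

    def test_exact_circle_recovered_to_machine_precision(self):
        pts = self.tilted_circle()
        fit = M.fit_circle(pts)
        assert fit.radius == pytest.approx(0.0187, abs=1e-9)
        assert np.max(np.abs(fit.s)) < 1e-9
        assert np.max(fit.plane.distances) < 1e-9

    def test_noisy_circle_matches_independent_optimizer(self, rng):
        pts = self.tilted_circle(noise=3e-4, rng=rng, tilt=0.0)
        fit = M.fit_circle(pts, M.fit_plane(pts, method="tls"))
        uv = fit.plane.project(pts)

        def cost(p):
            return np.sum((np.hypot(uv[:, 0] - p[0], uv[:, 1] - p[1]) - p[2]) ** 2)

        oracle = minimize(cost, x0=[0.001, -0.001, 0.015], method="Nelder-Mead",
                          options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000})
        assert fit.radius == pytest.approx(oracle.x[2], abs=1e-6)
        assert np.allclose(fit.center_uv, oracle.x[:2], atol=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            M.fit_plane(pts)

    def test_ols_rejects_vertical_plane_but_auto_recovers(self):
        theta = np.linspace(0, 2, 100)
        pts = np.column_stack([np.cos(theta), np.zeros_like(theta), np.sin(theta)])
        with pytest.raises(ValueError, match="vertical"):
            M.fit_plane(pts, method="ols")
        fit = M.fit_plane(pts, method="auto")
        assert np.max(fit.plane_distances if hasattr(fit, "plane_distances") else fit.distances) < 1e-9


class TestCircleDeviation:
    def test_on_circle_arc_is_zero(self):
        pts = TestPlaneAndCircleFits.tilted_circle(arc=2.0)
        fit = M.fit_circle(pts)
        assert M.circle_deviation(fit) < 1e-18

    def test_constant_offset_closed_form(self):
        # arc at radius r + s0 scored against a reference circle of radius r
        r, s0, arc = 0.012, 0.002, 1.8
        theta = np.linspace(0, arc, 300)
        plane = M.fit_plane(
            np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)]) * r
        )
        fit = M.CircleFit(
            plane=plane,
            center_uv=np.zeros(2),
            radius=r,
            s=np.full_like(theta, s0),
            theta=theta,
        )
        # sum s0^2 dtheta / (r * arc) = s0^2 / r
        assert M.circle_deviation(fit) == pytest.approx(s0**2 / r, rel=1e-6)

    def test_nominal_radius_mode_rescales_normalizer(self):
        pts = TestPlaneAndCircleFits.tilted_circle(arc=2.0, noise=2e-4,
                                                   rng=np.random.default_rng(5), tilt=0.0)
        fit = M.fit_circle(pts)
        default = M.circle_deviation(fit)
        nominal = M.circle_deviation(fit, radius=2 * fit.radius)
        assert nominal == pytest.approx(default / 2, rel=1e-9)

    def test_spatial_scaling_linear(self, rng):
        pts = TestPlaneAndCircleFits.tilted_circle(noise=2e-4, rng=rng, arc=2.5, tilt=0.2)
        c = 3.7
        d1 = M.circle_deviation(M.fit_circle(pts))
        d2 = M.circle_deviation(M.fit_circle(pts * c))
        assert d2 == pytest.approx(c * d1, rel=1e-6)


class TestPlaneDeviation:
    def test_planar_path_is_zero(self, rng):
        xy = rng.normal(0, 0.01, (50, 2)).cumsum(axis=0)
        pts = np.column_stack([xy, 0.3 * xy[:, 0] - 0.2 * xy[:, 1] + 0.01])
        fit = M.fit_plane(pts)
        assert M.plane_deviation(fit, pts) < 1e-20

    def test_sinusoidal_ripple_matches_independent_quadrature(self):
        # independent oracle: explicit normal-equation plane + weighted sum
        t = np.linspace(0, 1, 400)
        pts = np.column_stack(
            [0.1 * t, 0.03 * np.sin(2 * np.pi * t), 0.002 * np.sin(6 * np.pi * t)]
        )
        value = M.plane_deviation(M.fit_plane(pts, method="ols"), pts)

        X = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
        coef = np.linalg.solve(X.T @ X, X.T @ pts[:, 2])
        r = np.abs(X @ coef - pts[:, 2]) / np.sqrt(coef[0] ** 2 + coef[1] ** 2 + 1)
        dx = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        oracle = np.sum(r[1:] ** 2 * dx) / np.sum(dx)
        assert value == pytest.approx(oracle, rel=1e-9)

    def test_spatial_scaling_quadratic(self, rng):
        t = np.linspace(0, 1, 300)
        pts = np.column_stack(
            [0.1 * t, 0.04 * np.sin(2 * np.pi * t), 0.003 * np.sin(5 * np.pi * t)]
        )
        pts += rng.normal(0, 1e-4, pts.shape)
        c = 2.9
        d1 = M.plane_deviation(M.fit_plane(pts, "tls"), pts)
        d2 = M.plane_deviation(M.fit_plane(pts * c, "tls"), pts * c)
        assert d2 == pytest.approx(c**2 * d1, rel=1e-9)


class TestAngularPath:
    def test_quarter_turn_over_ten_centimeters(self):
        angles = np.linspace(0, np.pi / 2, 100)
        quats = Rotation.from_rotvec(np.outer(angles, [0, 0, 1])).as_quat()[:, [3, 0, 1, 2]]
        assert M.angular_path(quats, 0.1) == pytest.approx((np.pi / 2) / 0.1, rel=1e-9)

    def test_constant_orientation_is_zero(self):
        quats = np.tile([1.0, 0, 0, 0], (50, 1))
        assert M.angular_path(quats, 0.2) == 0.0

    def test_random_walk_matches_rotation_composition_oracle(self, rng):
        rotvecs = rng.normal(0, 0.05, (80, 3)).cumsum(axis=0)
        rots = Rotation.from_rotvec(rotvecs)
        quats = rots.as_quat()[:, [3, 0, 1, 2]]
        oracle = sum(
            (rots[i].inv() * rots[i + 1]).magnitude() for i in range(len(rots) - 1)
        )
        assert M.angular_path(quats, 1.0) == pytest.approx(oracle, rel=1e-9)


class TestCurvatureTorsion:
    def test_planar_circle_constant_speed(self):
        R, w = 0.05, 2.0
        t = np.linspace(0, 3, 300)
        v = np.column_stack([-R * w * np.sin(w * t), R * w * np.cos(w * t), 0 * t])
        a = np.column_stack([-R * w**2 * np.cos(w * t), -R * w**2 * np.sin(w * t), 0 * t])
        j = np.column_stack([R * w**3 * np.sin(w * t), -R * w**3 * np.cos(w * t), 0 * t])
        kappa, torsion, valid = M.curvature_torsion(v, a, j)
        assert valid.all()
        assert np.allclose(kappa, 1 / R, rtol=1e-9)
        assert np.allclose(torsion, 0.0, atol=1e-9)

    def test_helix_textbook_closed_form(self):
        R, c, w = 0.03, 0.01, 3.0
        t = np.linspace(0, 2, 200)
        v = np.column_stack([-R * w * np.sin(w * t), R * w * np.cos(w * t), np.full_like(t, c * w)])
        a = np.column_stack([-R * w**2 * np.cos(w * t), -R * w**2 * np.sin(w * t), 0 * t])
        j = np.column_stack([R * w**3 * np.sin(w * t), -R * w**3 * np.cos(w * t), 0 * t])
        kappa, torsion, valid = M.curvature_torsion(v, a, j)
        assert valid.all()
        assert np.allclose(kappa, R / (R**2 + c**2), rtol=1e-9)
        assert np.allclose(torsion, c / (R**2 + c**2), rtol=1e-9)

    def test_straight_line_flagged_invalid(self):
        n = 50
        v = np.tile([0.1, 0.0, 0.0], (n, 1))
        a = np.zeros((n, 3))
        j = np.zeros((n, 3))
        _, _, valid = M.curvature_torsion(v, a, j)
        assert not valid.any()


class TestPowerLawFit:
    def test_constant_speed_trajectory_has_null_exponents(self):
        from needledrive.synthetic import generate_powerlaw_trajectory

        trial = generate_powerlaw_trajectory(0.08, 0.0, 0.0)
        fit = M.fit_power_law(trial)
        assert abs(fit.beta) < 1e-6 and abs(fit.gamma) < 1e-6
        assert fit.alpha == pytest.approx(0.08, rel=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        from needledrive.synthetic import generate_powerlaw_trajectory

        trial = generate_powerlaw_trajectory(0.05, -0.3, -0.2)
        # perturb the kinematics so the fit is nontrivial
        trial.velocity = trial.velocity * np.exp(rng.normal(0, 0.05, (len(trial), 1)))
        fit = M.fit_power_law(trial)

        kappa, torsion, valid = M.curvature_torsion(
            trial.velocity, trial.acceleration, trial.jerk
        )
        speed = np.linalg.norm(trial.velocity, axis=1)
        use = valid & (np.abs(torsion) >= 1e-6) & (kappa > 0) & (speed > 1e-4)
        X = np.column_stack(
            [np.ones(use.sum()), np.log(kappa[use]), np.log(np.abs(torsion[use]))]
        )
        y = np.log(speed[use])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.alpha == pytest.approx(np.exp(coef[0]), abs=1e-9)
        assert fit.beta == pytest.approx(coef[1], abs=1e-9)
        assert fit.gamma == pytest.approx(coef[2], abs=1e-9)

    def test_insufficient_samples_rejected(self):
        n = 30
        t = np.arange(n) / 100
        trial = make_uniform_trial(
            t, np.zeros((n, 3)),
            velocity=np.tile([0.1, 0, 0], (n, 1)),
            acceleration=np.zeros((n, 3)), jerk=np.zeros((n, 3)),
        )
        with pytest.raises(ValueError, match="valid samples"):
            M.fit_power_law(trial)


class TestRmsJerk:
    def test_constant_jerk_magnitude(self):
        n = 200
        t = np.arange(n) / 100
        j0 = 4.2
        jerk = np.tile([j0 / np.sqrt(3)] * 3, (n, 1))
        trial = make_uniform_trial(t, np.zeros((n, 3)), jerk=jerk)
        seg = whole_trial_segment(trial)
        assert M.rms_jerk(seg) == pytest.approx(j0, rel=1e-12)

    def test_minimum_jerk_reach_matches_quadrature_oracle(self):
        D, T = 0.15, 1.2
        fs = 1000.0
        t = np.arange(0, T + 1 / fs / 2, 1 / fs)
        s = t / T
        jerk_analytic = D / T**3 * (60 - 360 * s + 360 * s**2)
        jerk = np.column_stack([jerk_analytic, 0 * t, 0 * t])
        trial = make_uniform_trial(t, np.zeros((len(t), 3)), jerk=jerk, rate=fs)
        seg = whole_trial_segment(trial)

        integral, _ = quad(lambda u: (D / T**3 * (60 - 360 * u / T + 360 * (u / T) ** 2)) ** 2, 0, T)
        oracle = np.sqrt(integral / T)
        assert M.rms_jerk(seg) == pytest.approx(oracle, rel=1e-5)

    def test_time_dilation_scales_as_inverse_cube(self):
        n, c = 500, 1.9
        t = np.arange(n) / 100
        jerk = np.column_stack([np.sin(2 * np.pi * t), np.cos(np.pi * t), 0 * t])
        base = whole_trial_segment(make_uniform_trial(t, np.zeros((n, 3)), jerk=jerk))
        dil = whole_trial_segment(
            make_uniform_trial(c * t, np.zeros((n, 3)), jerk=jerk / c**3, rate=100 / c)
        )
        assert M.rms_jerk(dil) == pytest.approx(M.rms_jerk(base) / c**3, rel=1e-12)

    def test_zero_duration_rejected(self):
        n = 10
        t = np.arange(n) / 100
        trial = make_uniform_trial(t, np.zeros((n, 3)), jerk=np.zeros((n, 3)))
        seg = whole_trial_segment(trial)
        seg.bounds = (3, 3)
        with pytest.raises(ValueError, match="duration"):
            M.rms_jerk(seg)


class TestRigidMotionInvariance:
    @staticmethod
    def random_smooth_path(rng, n=300):
        t = np.linspace(0, 1, n)
        return np.column_stack([
            0.05 * np.sin(2 * np.pi * t) + 0.01 * np.sin(5 * np.pi * t),
            0.04 * np.cos(2 * np.pi * t),
            0.01 * np.sin(3 * np.pi * t),
        ]) + rng.normal(0, 2e-4, (n, 3))

    def test_invariants_under_rotation_and_translation(self, rng):
        path = self.random_smooth_path(rng)
        rot = Rotation.from_rotvec(rng.normal(0, 1, 3)).as_matrix()
        offset = rng.normal(0, 0.5, 3)
        moved = path @ rot.T + offset

        assert M.path_length(moved) == pytest.approx(M.path_length(path), rel=1e-9)
        pd1 = M.plane_deviation(M.fit_plane(path, "tls"), path)
        pd2 = M.plane_deviation(M.fit_plane(moved, "tls"), moved)
        assert pd2 == pytest.approx(pd1, rel=1e-9)
        cd1 = M.circle_deviation(M.fit_circle(path, M.fit_plane(path, "tls")))
        cd2 = M.circle_deviation(M.fit_circle(moved, M.fit_plane(moved, "tls")))
        assert cd2 == pytest.approx(cd1, rel=1e-6)

    def test_consistency_invariant_when_profiles_co_rotated(self, rng):
        profiles = [self.random_smooth_path(rng, 60) for _ in range(3)]
        rot = Rotation.from_rotvec(rng.normal(0, 1, 3)).as_matrix()
        offset = rng.normal(0, 0.1, 3)
        moved = [p @ rot.T + offset for p in profiles]
        assert M.dtw_consistency(moved) == pytest.approx(
            M.dtw_consistency(profiles), rel=1e-9
        )

    def test_angular_path_invariant_under_global_rotation(self, rng):
        rotvecs = rng.normal(0, 0.05, (60, 3)).cumsum(axis=0)
        rots = Rotation.from_rotvec(rotvecs)
        g = Rotation.from_rotvec(rng.normal(0, 1, 3))
        quats = rots.as_quat()[:, [3, 0, 1, 2]]
        moved = (g * rots).as_quat()[:, [3, 0, 1, 2]]
        assert M.angular_path(moved, 0.37) == pytest.approx(
            M.angular_path(quats, 0.37), rel=1e-9
        )

    def test_spatial_scaling_exponents(self, rng):
        path = self.random_smooth_path(rng)
        c = 2.3
        assert M.path_length(c * path) == pytest.approx(c * M.path_length(path), rel=1e-12)
        ap1 = M.angular_path(np.tile([1.0, 0, 0, 0], (len(path), 1)), M.path_length(path))
        # angular path scales as 1/c through its path-length normalizer
        angles = np.linspace(0, 1.0, len(path))
        quats = Rotation.from_rotvec(np.outer(angles, [0, 1, 0])).as_quat()[:, [3, 0, 1, 2]]
        a1 = M.angular_path(quats, M.path_length(path))
        a2 = M.angular_path(quats, M.path_length(c * path))
        assert a2 == pytest.approx(a1 / c, rel=1e-12)


class TestIdealInsertionMetrics:
    def test_noiseless_arc_has_zero_deviations(self, noiseless_config):
        trial = generate_ideal_insertion(noiseless_config)
        fit = M.fit_circle(trial.position)
        assert M.circle_deviation(fit) < 1e-18
        assert M.plane_deviation(fit.plane, trial.position) < 1e-18

    def test_noiseless_arc_length_matches_analytic(self, noiseless_config):
        trial = generate_ideal_insertion(noiseless_config)
        expected = noiseless_config.needle_radius * noiseless_config.arc_span
        assert M.path_length(trial.position) == pytest.approx(expected, rel=1e-4)
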