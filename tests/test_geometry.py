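"""Head-rotation kinematics and gaze-screen projection."""

import numpy as np
import pytest
from scipy.linalg import expm

from collikinetics.geometry import (
    BehindScreenError,
    EulerAngles,
    GazeRay,
    GeometryConfig,
    GimbalLockError,
    InvalidModelError,
    NoIntersectionError,
    ScreenPlane,
    compensatory_yaw_correction,
    euler_from_rotation,
    eye_in_head_correction,
    gaze_screen_intersection,
    identity_correction,
    integrate_gyro,
    project_displacement_to_gaze_path,
    rodrigues_rotate,
    rotation_from_euler,
)


def elementary_product(phi, theta, psi):
    """Independent oracle: product of the three elementary DCM rotations."""
    rx = np.array(
        [[1, 0, 0], [0, np.cos(phi), np.sin(phi)], [0, -np.sin(phi), np.cos(phi)]]
    )
    ry = np.array(
        [[np.cos(theta), 0, -np.sin(theta)], [0, 1, 0], [np.sin(theta), 0, np.cos(theta)]]
    )
    rz = np.array(
        [[np.cos(psi), np.sin(psi), 0], [-np.sin(psi), np.cos(psi), 0], [0, 0, 1]]
    )
    return rx @ ry @ rz


class TestRotationFromEuler:
    def test_zero_angles_give_identity(self):
        assert np.allclose(rotation_from_euler(EulerAngles(0, 0, 0)), np.eye(3))

    def test_pure_yaw_quarter_turn(self):
        R = rotation_from_euler(EulerAngles(0, 0, np.pi / 2))
        assert abs(R[0, 0]) < 1e-12
        assert abs(R[0, 1] - 1.0) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementary_rotation_product(self, seed):
        rng = np.random.default_rng(seed)
        phi, theta, psi = rng.uniform(-np.pi + 0.1, np.pi - 0.1, 3)
        theta = np.clip(theta, -np.pi / 2 + 0.1, np.pi / 2 - 0.1)
        R = rotation_from_euler(EulerAngles(phi, theta, psi))
        assert np.allclose(R, elementary_product(phi, theta, psi), atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            EulerAngles(np.nan, 0, 0)

    def test_orthonormal_and_proper(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = EulerAngles(*rng.uniform(-3, 3, 3))
            R = rotation_from_euler(a)
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(R) - 1.0) < 1e-9


class TestEulerFromRotation:
    def test_identity_gives_zero_angles(self):
        a = euler_from_rotation(np.eye(3))
        assert (a.phi, a.theta, a.psi) == (0, 0, 0)

    def test_round_trip(self):
        a = EulerAngles(0.3, -0.2, 1.1)
        b = euler_from_rotation(rotation_from_euler(a))
        assert np.allclose([b.phi, b.theta, b.psi], [0.3, -0.2, 1.1], atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random(self, seed):
        rng = np.random.default_rng(seed)
        phi, psi = rng.uniform(-np.pi + 1e-3, np.pi - 1e-3, 2)
        theta = rng.uniform(-np.pi / 2 + 1e-3, np.pi / 2 - 1e-3)
        R = rotation_from_euler(EulerAngles(phi, theta, psi))
        b = euler_from_rotation(R)
        assert np.allclose(
            rotation_from_euler(b), R, atol=1e-9
        )

    def test_gimbal_lock_raises(self):
        R = rotation_from_euler(EulerAngles(0.0, -np.pi / 2, 0.0))
        with pytest.raises(GimbalLockError):
            euler_from_rotation(R)


class TestIntegrateGyro:
    def test_zero_rate_is_constant(self):
        R0 = rotation_from_euler(EulerAngles(0.1, 0.2, 0.3))
        out = integrate_gyro(R0, np.zeros((100, 3)), 1e-3)
        assert np.allclose(out[-1], R0, atol=1e-9)

    def test_constant_yaw_rate(self):
        om = np.tile([0.0, 0.0, 0.5], (20000, 1))
        out = integrate_gyro(np.eye(3), om, 1e-4)
        psi = euler_from_rotation(out[-1]).psi
        assert abs(psi - 1.0) < 1e-3

    def test_general_rate_matches_matrix_exponential(self):
        w = np.array([0.3, -0.4, 0.2])
        T, dt = 1.0, 1e-4
        out = integrate_gyro(np.eye(3), np.tile(w, (int(T / dt), 1)), dt)
        skew = np.array(
            [[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]]
        )
        expected = expm(skew * T).T   # update acts on R^T
        assert np.allclose(out[-1], expected, atol=5 * dt)

    def test_stays_on_rotation_manifold(self):
        rng = np.random.default_rng(0)
        om = rng.normal(0, 2.0, (2000, 3))
        out = integrate_gyro(np.eye(3), om, 1e-3)
        for R in out[::200]:
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            integrate_gyro(np.eye(3), np.zeros((1, 3)), 0.0)


def raymarch_oracle(ray, R, plane, m_max=500.0):
    """Numeric oracle: march the ray, bracket the residual sign change, refine."""
    p0 = R @ ray.origin_head
    d = R @ ray.direction_head
    ms = np.linspace(0.0, m_max, 4096)
    res = plane.y0 * (p0[0] + ms * d[0] - plane.x0) + plane.x0 * (p0[1] + ms * d[1])
    sign_change = np.flatnonzero(np.sign(res[:-1]) != np.sign(res[1:]))
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    lo, hi = ms[i], ms[i + 1]
    for _ in range(3):
        ms = np.linspace(lo, hi, 4096)
        res = plane.y0 * (p0[0] + ms * d[0] - plane.x0) + plane.x0 * (
            p0[1] + ms * d[1]
        )
        i = np.flatnonzero(np.sign(res[:-1]) != np.sign(res[1:]))[0]
        lo, hi = ms[i], ms[i + 1]
    return p0 + 0.5 * (lo + hi) * d


class TestGazeScreenIntersection:
    def test_point_lies_on_plane(self):
        plane = ScreenPlane(20.0, 20.0)
        ray = GazeRay(np.zeros(3), np.array([1.0, 0.0, 0.0]))
        p = gaze_screen_intersection(ray, np.eye(3), plane)
        assert abs(plane.residual(p)) < 1e-9

    def test_agrees_with_raymarch_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            R = rotation_from_euler(EulerAngles(*rng.uniform(-0.6, 0.6, 3)))
            plane = ScreenPlane(rng.uniform(5, 40), rng.uniform(5, 40))
            ray = GazeRay(rng.uniform(-2, 2, 3), np.array([1.0, 0.0, 0.0]))
            try:
                p = gaze_screen_intersection(ray, R, plane)
            except (NoIntersectionError, BehindScreenError):
                continue
            q = raymarch_oracle(ray, R, plane)
            if q is None:
                continue
            assert np.linalg.norm(p - q) < 1e-6
            checked += 1

    def test_parallel_ray_raises(self):
        plane = ScreenPlane(20.0, 20.0)  # normal (1, 1, 0)/sqrt(2)
        d = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)  # lies in the plane
        ray = GazeRay(np.array([0.0, 5.0, 0.0]), d)
        with pytest.raises(NoIntersectionError):
            gaze_screen_intersection(ray, np.eye(3), plane)

    def test_behind_screen_raises(self):
        plane = ScreenPlane(20.0, 20.0)
        ray = GazeRay(np.zeros(3), np.array([-1.0, 0.0, 0.0]))
        with pytest.raises(BehindScreenError):
            gaze_screen_intersection(ray, np.eye(3), plane)


class TestRodrigues:
    def test_zero_angle_is_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(rodrigues_rotate(v, 0.0), v)

    def test_quarter_turn_about_z(self):
        assert np.allclose(
            rodrigues_rotate(np.array([1.0, 0, 0]), np.pi / 2), [0, 1, 0], atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_axis_angle_matrix(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 1, 3)
        beta = rng.uniform(-np.pi, np.pi)
        c, s = np.cos(beta), np.sin(beta)
        Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        assert np.allclose(rodrigues_rotate(v, beta), Rz @ v, atol=1e-12)
        assert abs(np.linalg.norm(rodrigues_rotate(v, beta)) - np.linalg.norm(v)) < 1e-12


class TestEyeCorrection:
    def test_identity_model_leaves_direction(self):
        d = np.array([1.0, 0.0, 0.0])
        out = eye_in_head_correction(d, EulerAngles(0.1, 0.2, 0.3), identity_correction)
        assert np.allclose(out, d)

    def test_invalid_model_raises(self):
        bad = lambda angles: np.eye(3) * 2.0
        with pytest.raises(InvalidModelError):
            eye_in_head_correction(
                np.array([1.0, 0, 0]), EulerAngles(0, 0, 0.5), bad
            )

    def test_gain_one_cancels_yaw(self):
        """Full compensatory gain keeps lab-frame gaze azimuth fixed under yaw."""
        model = compensatory_yaw_correction(1.0)
        for psi in (0.2, -0.7, 1.1):
            a = EulerAngles(0.0, 0.0, psi)
            R = rotation_from_euler(a)
            d = eye_in_head_correction(np.array([1.0, 0, 0]), a, model)
            lab = R @ d
            assert np.allclose(lab, [1.0, 0.0, 0.0], atol=1e-12)


class TestGazePath:
    def test_zero_displacement_constant_path(self):
        t = np.linspace(-0.5, 1.0, 76)
        z = np.zeros_like(t)
        p = project_displacement_to_gaze_path(t, z, z, z)
        assert p.points.shape == (76, 2)
        assert np.allclose(p.points, 0.0, atol=1e-12)

    def test_pure_yaw_is_horizontal(self):
        t = np.linspace(-0.5, 1.0, 76)
        yaw = np.where(t > 0, 20 * t, 0.0)
        z = np.zeros_like(t)
        p = project_displacement_to_gaze_path(t, yaw, z, z)
        assert np.ptp(p.points[:, 1]) < 1e-6
        assert np.ptp(p.points[:, 0]) > 1.0

    def test_pure_pitch_is_vertical(self):
        t = np.linspace(-0.5, 1.0, 76)
        pitch = np.where(t > 0, 20 * t, 0.0)
        z = np.zeros_like(t)
        p = project_displacement_to_gaze_path(t, z, pitch, z)
        assert np.ptp(p.points[:, 0]) < 1e-6
        assert np.ptp(p.points[:, 1]) > 1.0

    def test_gain_one_compensation_removes_yaw_track(self):
        t = np.linspace(-0.5, 1.0, 76)
        yaw = np.where(t > 0, 20 * t, 0.0)
        z = np.zeros_like(t)
        cfg = GeometryConfig(correction=compensatory_yaw_correction(1.0))
        p = project_displacement_to_gaze_path(t, yaw, z, z, cfg)
        assert np.ptp(p.points[:, 0]) < 1e-9

    def test_offscreen_truncates_with_warning(self):
        t = np.linspace(-0.5, 1.0, 76)
        yaw = np.where(t > 0, 200 * t, 0.0)   # swings past the screen plane
        z = np.zeros_like(t)
        with pytest.warns(UserWarning):
            p = project_displacement_to_gaze_path(t, yaw, z, z)
        assert p.points.shape[0] < 76
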