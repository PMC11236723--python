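"""3D head-rotation kinematics and gaze projection onto the stimulus screen.

Head orientation is parameterized by aerospace (ZYX intrinsic) Euler angles:
yaw ``psi`` about the lab vertical axis, pitch ``theta`` about the
intermediate y axis, roll ``phi`` about the forward axis.  The direction
cosine matrix built here maps head-frame vectors into the lab frame.  A gaze
ray fixed in the head frame (pupil offset plus unit gaze direction) is
rotated by the instantaneous head orientation and intersected with a
vertical screen plane; the resulting track on the screen is rotated about
the lab vertical axis so the screen becomes frontoparallel, yielding 2D
screen coordinates.

All angles are radians internally; degrees appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EulerAngles",
    "ScreenPlane",
    "GazeRay",
    "GazePath2D",
    "GeometryConfig",
    "DEFAULT_GEOMETRY",
    "GimbalLockError",
    "NoIntersectionError",
    "BehindScreenError",
    "InvalidModelError",
    "rotation_from_euler",
    "euler_from_rotation",
    "integrate_gyro",
    "gaze_screen_intersection",
    "rodrigues_rotate",
    "identity_correction",
    "compensatory_yaw_correction",
    "eye_in_head_correction",
    "project_displacement_to_gaze_path",
]


class GimbalLockError(ValueError):
    """Pitch at +/-90 deg: yaw and roll are not separable."""


class NoIntersectionError(ValueError):
    """Gaze ray parallel to the screen plane."""


class BehindScreenError(ValueError):
    """Ray-plane solution has negative ray parameter (gaze points away)."""


class InvalidModelError(ValueError):
    """Eye-correction model emitted a non-rotation matrix."""


@dataclass(frozen=True)
class EulerAngles:
    """Roll ``phi``, pitch ``theta``, yaw ``psi`` in radians."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        for v in (self.phi, self.theta, self.psi):
            if not np.isfinite(v):
                raise ValueError("Euler angles must be finite")


@dataclass(frozen=True)
class ScreenPlane:
    """Vertical screen plane through (x0, 0, z) with in-plane normal (y0, x0, 0).

    The plane satisfies y0*(x - x0) + x0*y = 0 in lab coordinates and always
    contains the lab vertical direction.
    """

    x0: float
    y0: float

    def __post_init__(self) -> None:
        if self.x0 == 0.0 and self.y0 == 0.0:
            raise ValueError("screen plane requires (x0, y0) != (0, 0)")

    @property
    def normal(self) -> np.ndarray:
        n = np.array([self.y0, self.x0, 0.0])
        return n / np.linalg.norm(n)

    def residual(self, p: np.ndarray) -> float:
        """Signed plane-equation residual y0*(x - x0) + x0*y."""
        return self.y0 * (p[0] - self.x0) + self.x0 * p[1]

    @property
    def alignment_angle(self) -> float:
        """Rotation about the lab z axis making the screen frontoparallel."""
        return float(np.arcsin(self.y0 / np.hypot(self.x0, self.y0)))


@dataclass(frozen=True)
class GazeRay:
    """Pupil position and unit gaze direction, both in the head frame."""

    origin_head: np.ndarray
    direction_head: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin_head, dtype=float)
        d = np.asarray(self.direction_head, dtype=float)
        if o.shape != (3,) or d.shape != (3,):
            raise ValueError("origin and direction must be 3-vectors")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("gaze direction must be a unit vector")
        object.__setattr__(self, "origin_head", o)
        object.__setattr__(self, "direction_head", d)


@dataclass
class GazePath2D:
    """Screen-plane gaze track: times (s, relative to the spike) and 2D points."""

    times: np.ndarray
    points: np.ndarray  # (n, 2): horizontal, vertical, centred on t = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (self.times.size, 2):
            raise ValueError("points must be (n, 2) matching times")


# An eye-correction model maps head Euler angles to a rotation applied to the
# head-frame gaze direction (compensatory eye-in-head movement).
CorrectionModel = Callable[[EulerAngles], np.ndarray]


def identity_correction(angles: EulerAngles) -> np.ndarray:
    """Eye fixed in the head: no correction."""
    return np.eye(3)


def compensatory_yaw_correction(gain: float = 1.0) -> CorrectionModel:
    """Eye counter-rotates in yaw with the given gain (0 = none, 1 = full VOR).

    Returns a model rotating the head-frame gaze direction about the head z
    axis so as to oppose the head's yaw rotation (under the direction-cosine
    convention in use, head yaw ``psi`` turns the lab-frame gaze by ``-psi``
    about z, so the compensation is ``+gain * psi``); at gain 1 the lab-frame
    gaze azimuth is invariant to yaw.
    """

    def model(angles: EulerAngles) -> np.ndarray:
        a = gain * angles.psi
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    return model


@dataclass
class GeometryConfig:
    """Resting head/eye/screen geometry.

    Defaults place the head-restrained mouse 20 cm from a screen spanning
    31 deg down, 42 deg up, 45 deg nasal and 59 deg temporal of the resting
    gaze, with the resting gaze along the lab +x axis and the pupil at the
    head origin.  The screen-plane parameters (x0, y0) are in cm.
    """

    screen_distance: float = 20.0
    screen_plane: ScreenPlane = field(default_factory=lambda: ScreenPlane(20.0, 20.0))
    pupil_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gaze_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    extent_down_deg: float = 31.0
    extent_up_deg: float = 42.0
    extent_nasal_deg: float = 45.0
    extent_temporal_deg: float = 59.0
    correction: CorrectionModel = identity_correction

    @property
    def ray(self) -> GazeRay:
        d = np.asarray(self.gaze_direction, dtype=float)
        return GazeRay(np.asarray(self.pupil_offset, dtype=float), d / np.linalg.norm(d))


DEFAULT_GEOMETRY = GeometryConfig()


def rotation_from_euler(angles: EulerAngles) -> np.ndarray:
    """Direction cosine matrix for roll/pitch/yaw (ZYX convention).

    Entry-wise: R13 = -sin(theta), R23 = sin(phi) cos(theta),
    R33 = cos(phi) cos(theta).
    """
    cphi, sphi = np.cos(angles.phi), np.sin(angles.phi)
    cth, sth = np.cos(angles.theta), np.sin(angles.theta)
    cpsi, spsi = np.cos(angles.psi), np.sin(angles.psi)
    return np.array(
        [
            [cth * cpsi, cth * spsi, -sth],
            [sphi * sth * cpsi - cphi * spsi, sphi * sth * spsi + cphi * cpsi, sphi * cth],
            [cphi * sth * cpsi + sphi * spsi, cphi * sth * spsi - sphi * cpsi, cphi * cth],
        ]
    )


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-7)):
        raise ValueError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=max(tol, 1e-7)):
        raise ValueError("matrix determinant is not +1")
    return R


def euler_from_rotation(R: np.ndarray) -> EulerAngles:
    """Extract roll/pitch/yaw from a direction cosine matrix.

    phi = atan2(R23, R33), theta = -asin(R13), psi = atan2(R12, R11).
    Raises :class:`GimbalLockError` when |R13| is within 1e-9 of 1.
    """
    R = _check_rotation(R)
    if abs(R[0, 2]) >= 1.0 - 1e-9:
        raise GimbalLockError("pitch at +/-90 deg; Euler angles degenerate")
    return EulerAngles(
        phi=float(np.arctan2(R[1, 2], R[2, 2])),
        theta=float(-np.arcsin(np.clip(R[0, 2], -1.0, 1.0))),
        psi=float(np.arctan2(R[0, 1], R[0, 0])),
    )


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (polar decomposition via SVD)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def integrate_gyro(
    R0: np.ndarray,
    omega_series: np.ndarray,
    dt: float,
    renormalize: bool = True,
) -> np.ndarray:
    """Integrate body-frame angular rates into a rotation-matrix time series.

    Applies the first-order gyroscope update
    ``R^T(t+dt) = R^T(t) @ (I + [omega]_x dt)`` at each step.  The first-order
    step drifts off SO(3); with ``renormalize`` (the default) each result is
    projected back to the nearest rotation.

    Parameters
    ----------
    R0 : (3, 3) initial rotation.
    omega_series : (n, 3) angular rates (rad/s), body frame.
    dt : step in seconds, > 0.

    Returns
    -------
    (n + 1, 3, 3) array of rotations, starting with ``R0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    R0 = _check_rotation(R0)
    omega_series = np.atleast_2d(np.asarray(omega_series, dtype=float))
    out = np.empty((omega_series.shape[0] + 1, 3, 3))
    out[0] = R0
    Rt = R0.T.copy()
    for i, (wx, wy, wz) in enumerate(omega_series):
        update = np.array(
            [
                [1.0, -wz * dt, wy * dt],
                [wz * dt, 1.0, -wx * dt],
                [-wy * dt, wx * dt, 1.0],
            ]
        )
        Rt = Rt @ update
        if renormalize:
            Rt = _nearest_rotation(Rt)
        out[i + 1] = Rt.T
    return out


def gaze_screen_intersection(
    ray: GazeRay, R: np.ndarray, plane: ScreenPlane
) -> np.ndarray:
    """Lab-frame point where the rotated gaze ray meets the screen plane.

    The pupil position and gaze direction are rotated into the lab frame
    (P0 = R P0', d = R d'); the ray P0 + m d is substituted in the plane
    equation y0*(x - x0) + x0*y = 0 and solved for m.
    """
    R = np.asarray(R, dtype=float)
    p0 = R @ ray.origin_head
    d = R @ ray.direction_head
    denom = plane.y0 * d[0] + plane.x0 * d[1]
    if abs(denom) < 1e-12:
        raise NoIntersectionError("gaze ray parallel to the screen plane")
    m = (plane.y0 * (plane.x0 - p0[0]) - plane.x0 * p0[1]) / denom
    if m < 0:
        raise BehindScreenError("gaze points away from the screen")
    return p0 + m * d


def rodrigues_rotate(v: np.ndarray, beta: float) -> np.ndarray:
    """Rotate ``v`` about the lab z axis by ``beta`` (Rodrigues' formula).

    v_rot = v cos(beta) + (z x v) sin(beta) + z (z . v) (1 - cos(beta)).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)) or not np.isfinite(beta):
        raise ValueError("inputs must be finite")
    z = np.array([0.0, 0.0, 1.0])
    return (
        v * np.cos(beta)
        + np.cross(z, v) * np.sin(beta)
        + z * np.dot(z, v) * (1.0 - np.cos(beta))
    )


def eye_in_head_correction(
    direction: np.ndarray, angles: EulerAngles, model: CorrectionModel
) -> np.ndarray:
    """Apply an eye-in-head correction rotation to the head-frame gaze direction."""
    Rc = np.asarray(model(angles), dtype=float)
    try:
        _check_rotation(Rc)
    except ValueError as exc:
        raise InvalidModelError(str(exc)) from exc
    return Rc @ np.asarray(direction, dtype=float)


def project_displacement_to_gaze_path(
    times: np.ndarray,
    yaw_deg: np.ndarray,
    pitch_deg: np.ndarray,
    roll_deg: np.ndarray,
    config: GeometryConfig | None = None,
) -> GazePath2D:
    """Project cumulative head displacements into a 2D gaze track on the screen.

    The head is taken at rest (identity orientation) at the spike time
    (t = 0, where the displacement curves are zero by construction).  Each
    time bin's Euler displacement is converted to a rotation, the (optionally
    eye-corrected) gaze ray is intersected with the screen, and the point is
    rotated about the lab vertical so the screen is frontoparallel; the
    returned coordinates are (horizontal, vertical) relative to the t = 0
    calibration centre.  Bins whose ray misses the screen truncate the path
    (a warning is logged).
    """
    import warnings

    cfg = config if config is not None else DEFAULT_GEOMETRY
    times = np.asarray(times, dtype=float)
    disp = np.deg2rad(np.column_stack([roll_deg, pitch_deg, yaw_deg]))
    beta = cfg.screen_plane.alignment_angle
    base_ray = cfg.ray

    pts: list[np.ndarray] = []
    kept: list[float] = []
    for t, (phi, theta, psi) in zip(times, disp):
        angles = EulerAngles(phi=float(phi), theta=float(theta), psi=float(psi))
        R = rotation_from_euler(angles)
        d = eye_in_head_correction(base_ray.direction_head, angles, cfg.correction)
        ray = GazeRay(base_ray.origin_head, d / np.linalg.norm(d))
        try:
            p = gaze_screen_intersection(ray, R, cfg.screen_plane)
        except (NoIntersectionError, BehindScreenError):
            warnings.warn(
                f"gaze ray misses the screen at t={t:+.3f} s; path truncated",
                stacklevel=2,
            )
            break
        p_rot = rodrigues_rotate(p, beta)
        pts.append(np.array([p_rot[0], p_rot[2]]))
        kept.append(t)

    points = np.array(pts) if pts else np.empty((0, 2))
    if points.size:
        # centre on the calibration point (t = 0; displacements vanish there)
        i0 = int(np.argmin(np.abs(np.asarray(kept))))
        points = points - points[i0]
    return GazePath2D(times=np.asarray(kept), points=points)
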