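"""Per-sensor orientation and motion estimation.

Orientation is parameterised by Euler angles composed as
``R = Rx(theta_x) @ Ry(theta_y) @ Rz(theta_z)`` (the same order the
kinematic chain uses), stored in degrees, computed in radians.  A raw
gyroscope measures body-frame angular rate ``omega``, related to the Euler
angle rates by ``omega = M(theta) @ theta_dot``; gyro integration solves
this mapping with a second-order (Heun/trapezoid) step.

The accelerometer observes the gravity direction whenever the sensor is
quasi-static, which pins roll (theta_x) and pitch (theta_y) but never yaw
(theta_z): with no magnetometer, yaw is gyro-integrated and zeroed at each
session start.  The complementary filter blends the two sources with a
weight ``alpha`` (gyro-dominant, default 0.98 at 50 Hz); the Kalman variant
runs three decoupled angle+bias filters, one per axis.

Linear motion: gravity is rotated into the sensor frame and subtracted
(``a_real = a_measured - R(theta)^T @ (0, 0, g)``), then velocity and
position follow by trapezoid integration, optionally reset during detected
rest windows (ZUPT) to bound dead-reckoning drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imu_core import ImuSample, ImuStream, ValidationError

__all__ = [
    "GRAVITY",
    "GIMBAL_MARGIN_DEG",
    "OrientationSeries",
    "MotionState",
    "FilterConfig",
    "euler_to_matrix",
    "matrix_to_euler",
    "euler_rate_matrix",
    "integrate_gyro",
    "accel_tilt",
    "fuse_orientation",
    "remove_gravity",
    "integrate_motion",
    "detect_rest",
]

GRAVITY = 9.81  # m/s^2

#: entries with |theta_y| within this margin of 90 deg are gimbal-flagged
GIMBAL_MARGIN_DEG = 0.5


def euler_to_matrix(euler_deg) -> np.ndarray:
    """Rotation matrix R = Rx @ Ry @ Rz from (theta_x, theta_y, theta_z) degrees.

    Accepts a single triple or an (n, 3) array; returns (3, 3) or (n, 3, 3).
    """
    e = np.deg2rad(np.asarray(euler_deg, dtype=float))
    single = e.ndim == 1
    e = np.atleast_2d(e)
    ca, sa = np.cos(e[:, 0]), np.sin(e[:, 0])
    cb, sb = np.cos(e[:, 1]), np.sin(e[:, 1])
    cc, sc = np.cos(e[:, 2]), np.sin(e[:, 2])
    R = np.empty((e.shape[0], 3, 3))
    R[:, 0, 0] = cb * cc
    R[:, 0, 1] = -cb * sc
    R[:, 0, 2] = sb
    R[:, 1, 0] = ca * sc + sa * sb * cc
    R[:, 1, 1] = ca * cc - sa * sb * sc
    R[:, 1, 2] = -sa * cb
    R[:, 2, 0] = sa * sc - ca * sb * cc
    R[:, 2, 1] = sa * cc + ca * sb * sc
    R[:, 2, 2] = ca * cb
    return R[0] if single else R


def matrix_to_euler(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert :func:`euler_to_matrix`; returns (degrees triple, gimbal flag).

    Near theta_y = +/-90 deg the x/z rotations couple; the returned branch
    fixes theta_z = 0 there and the flag is set instead of raising.
    """
    r02 = float(np.clip(R[0, 2], -1.0, 1.0))
    theta_y = np.arcsin(r02)
    gimbal = abs(abs(r02) - 1.0) < 1e-9 or (90.0 - abs(np.rad2deg(theta_y))) < GIMBAL_MARGIN_DEG
    if abs(abs(r02) - 1.0) < 1e-9:
        # degenerate branch: only theta_x +/- theta_z observable
        theta_x = np.arctan2(R[1, 0], R[1, 1])
        theta_z = 0.0
    else:
        theta_x = np.arctan2(-R[1, 2], R[2, 2])
        theta_z = np.arctan2(-R[0, 1], R[0, 0])
    return np.rad2deg(np.array([theta_x, theta_y, theta_z])), bool(gimbal)


def euler_rate_matrix(euler_deg) -> np.ndarray:
    """M(theta) with omega_body = M @ theta_dot for the Rx@Ry@Rz convention.

    Singular (det = cos theta_y = 0) at the gimbal poles.
    """
    e = np.deg2rad(np.asarray(euler_deg, dtype=float))
    cb, sb = np.cos(e[1]), np.sin(e[1])
    cc, sc = np.cos(e[2]), np.sin(e[2])
    return np.array(
        [
            [cb * cc, sc, 0.0],
            [-cb * sc, cc, 0.0],
            [sb, 0.0, 1.0],
        ]
    )


def _euler_rates(euler_deg: np.ndarray, omega_deg_s: np.ndarray) -> np.ndarray:
    """Euler angle rates (deg/s) from body rates (deg/s) at a given attitude."""
    M = euler_rate_matrix(euler_deg)
    det = np.cos(np.deg2rad(euler_deg[1]))
    if abs(det) < 1e-8:  # gimbal pole: fall back to the naive identity mapping
        return np.asarray(omega_deg_s, dtype=float)
    return np.linalg.solve(M, np.asarray(omega_deg_s, dtype=float))


@dataclass
class OrientationSeries:
    """Euler angles (degrees) of one rigid body over time.

    ``gimbal`` flags entries with |theta_y| near 90 deg, where the Euler
    decomposition degenerates.
    """

    t: np.ndarray
    euler: np.ndarray  # (n, 3) degrees
    gimbal: np.ndarray = None  # (n,) bool

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.euler = np.asarray(self.euler, dtype=float)
        n = self.t.shape[0]
        if self.euler.shape != (n, 3):
            raise ValidationError(f"euler shape {self.euler.shape} != ({n}, 3)")
        if self.gimbal is None:
            self.gimbal = (90.0 - np.abs(self.euler[:, 1])) < GIMBAL_MARGIN_DEG
        self.gimbal = np.asarray(self.gimbal, dtype=bool)

    def __len__(self) -> int:
        return self.t.shape[0]

    def matrices(self) -> np.ndarray:
        return euler_to_matrix(self.euler)


@dataclass
class MotionState:
    """Gravity-free acceleration with its integrated velocity and position."""

    t: np.ndarray
    linear_accel: np.ndarray  # (n, 3) m/s^2
    velocity: np.ndarray  # (n, 3) m/s
    position: np.ndarray  # (n, 3) m
    gravity_mag: float = GRAVITY


@dataclass
class FilterConfig:
    """Orientation estimator settings.

    method: "complementary" (default), "kalman", or "gyro_only".
    alpha: complementary gyro weight in [0, 1]; 1 degenerates to gyro-only.
    q_angle/q_bias: Kalman process noise densities (deg^2/s) for the angle
    and gyro-bias states; r_angle: tilt measurement variance (deg^2).
    """

    method: str = "complementary"
    alpha: float = 0.98
    q_angle: float = 0.01
    q_bias: float = 0.003
    r_angle: float = 0.5
    gravity_mag: float = GRAVITY

    def __post_init__(self) -> None:
        if self.method not in ("complementary", "kalman", "gyro_only"):
            raise ValidationError(f"unknown fusion method {self.method!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if min(self.q_angle, self.q_bias, self.r_angle) <= 0:
            raise ValidationError("Kalman noise variances must be > 0")
        if self.gravity_mag <= 0:
            raise ValidationError("gravity_mag must be > 0")


def _check_dt(t: np.ndarray) -> np.ndarray:
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("non-positive time step in stream")
    return dt


def integrate_gyro(
    stream: ImuStream, initial_euler: Sequence[float] = (0.0, 0.0, 0.0)
) -> OrientationSeries:
    """Dead-reckon orientation from gyro rates alone.

    theta(t) = theta(t-1) + quadrature(theta_dot, dt) where the Euler rates
    come from the body-rate mapping; the step is Heun's method (trapezoid
    with an explicit predictor), second-order accurate.  Accurate over
    short spans, drifts with any rate bias.
    """
    dt = _check_dt(stream.t)
    n = len(stream)
    euler = np.empty((n, 3))
    euler[0] = np.asarray(initial_euler, dtype=float)
    for k in range(n - 1):
        f0 = _euler_rates(euler[k], stream.gyro[k])
        pred = euler[k] + dt[k] * f0
        f1 = _euler_rates(pred, stream.gyro[k + 1])
        euler[k + 1] = euler[k] + 0.5 * dt[k] * (f0 + f1)
    return OrientationSeries(t=stream.t.copy(), euler=euler)


def accel_tilt(
    sample: "ImuSample | np.ndarray",
    gravity_mag: float = GRAVITY,
    yaw_deg: float = 0.0,
    tol: float = 0.3,
) -> "tuple[float, float] | None":
    """Roll/pitch (theta_x, theta_y degrees) from the gravity direction.

    Valid only when the sensor is quasi-static: if the accel magnitude is
    outside ``(1 +/- tol) * gravity_mag`` the motion is dynamic and ``None``
    is returned.  Yaw is unobservable from gravity; because this Euler
    order applies yaw innermost, the measured vector is first de-rotated by
    the caller's yaw estimate (0 by default).
    """
    a = sample.accel if isinstance(sample, ImuSample) else np.asarray(sample, dtype=float)
    mag = float(np.linalg.norm(a))
    if not (1.0 - tol) * gravity_mag <= mag <= (1.0 + tol) * gravity_mag:
        return None
    c, s = np.cos(np.deg2rad(yaw_deg)), np.sin(np.deg2rad(yaw_deg))
    ax = c * a[0] - s * a[1]
    ay = s * a[0] + c * a[1]
    az = a[2]
    theta_x = np.arctan2(ay, np.hypot(ax, az))
    theta_y = np.arctan2(-ax, az)
    return float(np.rad2deg(theta_x)), float(np.rad2deg(theta_y))


def fuse_orientation(stream: ImuStream, config: FilterConfig | None = None) -> OrientationSeries:
    """Estimate orientation by blending gyro integration with accel tilt.

    complementary:  theta <- alpha*(theta + theta_dot*dt) + (1-alpha)*theta_tilt
    on roll/pitch (gyro-only on yaw); the tilt term is skipped whenever the
    accel magnitude flags dynamic motion.
    kalman: per-axis linear filters with state (angle, gyro-bias), gyro
    integration as process model and accel tilt as the measurement.
    gyro_only: identical to :func:`integrate_gyro`.
    """
    cfg = config or FilterConfig()
    if cfg.method == "gyro_only" or (cfg.method == "complementary" and cfg.alpha == 1.0):
        # alpha = 1 gives the accelerometer zero weight everywhere,
        # including the initial attitude
        return integrate_gyro(stream)

    dt = _check_dt(stream.t)
    n = len(stream)
    euler = np.empty((n, 3))
    tilt0 = accel_tilt(stream.accel[0], cfg.gravity_mag)
    euler[0] = (tilt0[0], tilt0[1], 0.0) if tilt0 is not None else (0.0, 0.0, 0.0)

    if cfg.method == "complementary":
        alpha = cfg.alpha
        for k in range(n - 1):
            f0 = _euler_rates(euler[k], stream.gyro[k])
            pred = euler[k] + dt[k] * f0
            f1 = _euler_rates(pred, stream.gyro[k + 1])
            gyro_step = euler[k] + 0.5 * dt[k] * (f0 + f1)
            tilt = accel_tilt(stream.accel[k + 1], cfg.gravity_mag, yaw_deg=gyro_step[2])
            euler[k + 1] = gyro_step
            if tilt is not None and alpha < 1.0:
                euler[k + 1, 0] = alpha * gyro_step[0] + (1.0 - alpha) * tilt[0]
                euler[k + 1, 1] = alpha * gyro_step[1] + (1.0 - alpha) * tilt[1]
        return OrientationSeries(t=stream.t.copy(), euler=euler)

    # kalman: three decoupled (angle, bias) filters; z has no measurement
    bias = np.zeros(3)
    P = np.tile(np.diag([1.0, 0.1]), (3, 1, 1))  # per-axis 2x2 covariance
    for k in range(n - 1):
        h = dt[k]
        f0 = _euler_rates(euler[k], stream.gyro[k] - bias)
        pred = euler[k] + h * f0
        f1 = _euler_rates(pred, stream.gyro[k + 1] - bias)
        angle_pred = euler[k] + 0.5 * h * (f0 + f1)
        F = np.array([[1.0, -h], [0.0, 1.0]])
        Q = np.diag([cfg.q_angle * h, cfg.q_bias * h])
        for ax in range(3):
            P[ax] = F @ P[ax] @ F.T + Q
        tilt = accel_tilt(stream.accel[k + 1], cfg.gravity_mag, yaw_deg=angle_pred[2])
        euler[k + 1] = angle_pred
        if tilt is not None:
            for ax, z in ((0, tilt[0]), (1, tilt[1])):
                S = P[ax][0, 0] + cfg.r_angle
                K = P[ax][:, 0] / S
                innov = z - angle_pred[ax]
                euler[k + 1, ax] = angle_pred[ax] + K[0] * innov
                # the angle-bias cross covariance is negative (F couples
                # them through -dt), so this gain already has the right sign
                bias[ax] += K[1] * innov
                P[ax] = (np.eye(2) - np.outer(K, [1.0, 0.0])) @ P[ax]
    return OrientationSeries(t=stream.t.copy(), euler=euler)


def remove_gravity(
    sample: "ImuSample | np.ndarray",
    euler_deg: Sequence[float],
    gravity_mag: float = GRAVITY,
) -> np.ndarray:
    """Gravity-free acceleration in the sensor frame.

    a_real = a_measured - R(theta)^T @ (0, 0, gravity_mag): the world
    gravity vector rotated into the sensor frame and subtracted.  A static,
    correctly-oriented sample yields ~0; a free-fall sample at level
    attitude yields (0, 0, -g).
    """
    a = sample.accel if isinstance(sample, ImuSample) else np.asarray(sample, dtype=float)
    R = euler_to_matrix(np.asarray(euler_deg, dtype=float))
    g_sensor = R.T @ np.array([0.0, 0.0, gravity_mag])
    return a - g_sensor


def integrate_motion(
    t: np.ndarray,
    linear_accel: np.ndarray,
    v0: Sequence[float] = (0.0, 0.0, 0.0),
    p0: Sequence[float] = (0.0, 0.0, 0.0),
    rest_mask: np.ndarray | None = None,
) -> MotionState:
    """Velocity and position by trapezoid integration of linear acceleration.

    v(t) = v(t-1) + integral(a dt);  p(t) = p(t-1) + integral(v dt).
    With ``rest_mask`` (ZUPT), velocity is reset to zero on rest samples,
    bounding the cubic-in-time drift of double integration.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(linear_accel, dtype=float)
    dt = _check_dt(t)
    n = t.shape[0]
    v = np.empty((n, 3))
    p = np.empty((n, 3))
    v[0] = np.asarray(v0, dtype=float)
    p[0] = np.asarray(p0, dtype=float)
    if rest_mask is not None:
        rest_mask = np.asarray(rest_mask, dtype=bool)
        if rest_mask[0]:
            v[0] = 0.0
    for k in range(n - 1):
        v[k + 1] = v[k] + 0.5 * dt[k] * (a[k] + a[k + 1])
        if rest_mask is not None and rest_mask[k + 1]:
            v[k + 1] = 0.0
        p[k + 1] = p[k] + 0.5 * dt[k] * (v[k] + v[k + 1])
    return MotionState(t=t, linear_accel=a, velocity=v, position=p)


def detect_rest(
    stream: ImuStream,
    gyro_thresh: float = 2.0,
    accel_thresh: float = 0.3,
    min_duration: float = 0.2,
    gravity_mag: float = GRAVITY,
) -> np.ndarray:
    """Boolean rest mask: gyro magnitude < 2 deg/s and | ||a|| - g | < 0.3
    m/s^2 sustained for at least ``min_duration`` seconds."""
    quiet = (np.linalg.norm(stream.gyro, axis=1) < gyro_thresh) & (
        np.abs(np.linalg.norm(stream.accel, axis=1) - gravity_mag) < accel_thresh
    )
    mask = np.zeros(len(stream), dtype=bool)
    k = 0
    n = len(stream)
    while k < n:
        if not quiet[k]:
            k += 1
            continue
        j = k
        while j < n and quiet[j]:
            j += 1
        if stream.t[j - 1] - stream.t[k] >= min_duration:
            mask[k:j] = True
        k = j
    return mask
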