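"""Homogeneous-transform algebra and the three-sensor arm model.

The hand–wrist–forearm system is modelled as a two-segment chain hinged at
the wrist rotation axis A: the hand segment AB (A to the middle-finger
point B, end point N) and the forearm segment AC (A to the elbow rotation
axis C, end point M).  Sensor S1 sits at A, S2 at the midpoint of AB, S3 at
the midpoint of AC, all aligned along the Y axis in the resting pose.

Rigid motions are 4x4 homogeneous transforms; a general pose is the
product ``T(dx,dy,dz) @ Rx(theta_x) @ Ry(theta_y) @ Rz(theta_z)``.  Wrist
angles are the Euler decomposition (same axis order) of the hand
orientation expressed in the forearm frame, R_forearm^T @ R_hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import (
    FilterConfig,
    OrientationSeries,
    euler_to_matrix,
    fuse_orientation,
    matrix_to_euler,
)
from .imu_core import SessionRecording, SyncResult, ValidationError, round_robin_sync

__all__ = [
    "HomogeneousTransform",
    "ArmModel",
    "JointAngleSeries",
    "HandPose",
    "translation",
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "rototranslate",
    "forward_kinematics",
    "relative_orientation",
    "wrist_angles",
]


class HomogeneousTransform:
    """A 4x4 rototranslation, validated on construction.

    Invariants: bottom row exactly (0, 0, 0, 1); rotation block orthonormal
    with determinant +1 to 1e-9.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"transform must be 4x4, got {m.shape}")
        if not np.array_equal(m[3], (0.0, 0.0, 0.0, 1.0)):
            raise ValidationError(f"bottom row must be (0,0,0,1), got {m[3]}")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation block is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation block determinant != +1 (reflection?)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "HomogeneousTransform":
        return cls(np.eye(4))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def __matmul__(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        return HomogeneousTransform(self.matrix @ other.matrix)

    def inverse(self) -> "HomogeneousTransform":
        R, d = self.rotation, self.translation_vector
        out = np.eye(4)
        out[:3, :3] = R.T
        out[:3, 3] = -R.T @ d
        return HomogeneousTransform(out)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one 3-point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation_vector
        return out[0] if single else out

    def __repr__(self) -> str:
        return f"HomogeneousTransform(\n{self.matrix})"

    def allclose(self, other: "HomogeneousTransform", atol: float = 1e-12) -> bool:
        return np.allclose(self.matrix, other.matrix, atol=atol)


def translation(dx: float, dy: float, dz: float) -> HomogeneousTransform:
    """Pure translation by (dx, dy, dz) metres."""
    m = np.eye(4)
    m[:3, 3] = (dx, dy, dz)
    return HomogeneousTransform(m)


def _rot(axis: int, theta_deg: float) -> HomogeneousTransform:
    th = np.deg2rad(float(theta_deg))
    c, s = np.cos(th), np.sin(th)
    m = np.eye(4)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[i, j] = -s
    m[j, i] = s
    m[j, j] = c
    return HomogeneousTransform(m)


def rotation_x(theta_deg: float) -> HomogeneousTransform:
    """Right-handed rotation about x by theta (degrees)."""
    return _rot(0, theta_deg)


def rotation_y(theta_deg: float) -> HomogeneousTransform:
    """Right-handed rotation about y by theta (degrees)."""
    return _rot(1, theta_deg)


def rotation_z(theta_deg: float) -> HomogeneousTransform:
    """Right-handed rotation about z by theta (degrees)."""
    return _rot(2, theta_deg)


def rototranslate(
    dx: float,
    dy: float,
    dz: float,
    theta_x: float = 0.0,
    theta_y: float = 0.0,
    theta_z: float = 0.0,
) -> HomogeneousTransform:
    """General pose: T(dx,dy,dz) @ Rx(theta_x) @ Ry(theta_y) @ Rz(theta_z),
    in exactly that order (angles in degrees)."""
    return translation(dx, dy, dz) @ rotation_x(theta_x) @ rotation_y(theta_y) @ rotation_z(theta_z)


@dataclass(frozen=True)
class ArmModel:
    """Segment lengths and sensor placements of one operator's arm.

    len_ab: wrist axis A to middle-finger point B (hand segment, metres).
    len_ac: A to elbow rotation axis C (forearm segment, metres).
    S1 sits at A, S2 at len_ab/2 along AB, S3 at len_ac/2 along AC; the
    resting pose aligns both segments with the Y axis (hand towards +Y).
    Defaults suit an average adult; override per operator in config.
    """

    len_ab: float = 0.18
    len_ac: float = 0.26

    def __post_init__(self) -> None:
        if self.len_ab <= 0 or self.len_ac <= 0:
            raise ValidationError("segment lengths must be > 0")

    @property
    def s2_offset(self) -> float:
        return self.len_ab / 2.0

    @property
    def s3_offset(self) -> float:
        return self.len_ac / 2.0


@dataclass(frozen=True)
class HandPose:
    """Forward-kinematics output: hand end point N and sensor point S2,
    both in the forearm frame anchored at the wrist axis A."""

    n_point: np.ndarray
    s2_point: np.ndarray
    transform: HomogeneousTransform


def forward_kinematics(model: ArmModel, wrist_euler_deg) -> HandPose:
    """Pose of the hand segment for given wrist angles.

    The hand segment of length ``len_ab`` is anchored at A and rotated by
    ``rototranslate(0, 0, 0, theta_x, theta_y, theta_z)``; segment lengths
    are preserved for every input (rigid body).
    """
    tx, ty, tz = np.asarray(wrist_euler_deg, dtype=float)
    T = rototranslate(0.0, 0.0, 0.0, tx, ty, tz)
    rest_dir = np.array([0.0, 1.0, 0.0])
    return HandPose(
        n_point=T.apply(rest_dir * model.len_ab),
        s2_point=T.apply(rest_dir * model.s2_offset),
        transform=T,
    )


@dataclass
class JointAngleSeries:
    """Wrist angles (hand relative to forearm) per synchronized frame,
    signed degrees per axis; gimbal entries flagged, not dropped."""

    t: np.ndarray
    euler: np.ndarray  # (n, 3) degrees
    gimbal: np.ndarray = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.euler = np.asarray(self.euler, dtype=float)
        if self.euler.shape != (self.t.shape[0], 3):
            raise ValidationError("euler shape mismatch with t")
        if self.gimbal is None:
            self.gimbal = np.zeros(self.t.shape[0], dtype=bool)
        self.gimbal = np.asarray(self.gimbal, dtype=bool)

    def __len__(self) -> int:
        return self.t.shape[0]


def relative_orientation(
    hand: OrientationSeries, forearm: OrientationSeries
) -> JointAngleSeries:
    """Per-frame Euler decomposition of R_forearm^T @ R_hand.

    Both series must lie on the same synchronized grid.  Identical series
    give zero angles; a common rotation of both segments cancels.
    """
    if len(hand) != len(forearm) or not np.allclose(hand.t, forearm.t, atol=1e-9):
        raise ValidationError("hand and forearm series are not on the same grid")
    Rh = hand.matrices()
    Rf = forearm.matrices()
    n = len(hand)
    euler = np.empty((n, 3))
    gimbal = np.zeros(n, dtype=bool)
    for k in range(n):
        euler[k], gimbal[k] = matrix_to_euler(Rf[k].T @ Rh[k])
    return JointAngleSeries(t=hand.t.copy(), euler=euler, gimbal=gimbal)


def wrist_angles(
    session: "SessionRecording | SyncResult",
    config: FilterConfig | None = None,
    rate: float | None = None,
) -> JointAngleSeries:
    """Full pipeline: synchronize, fuse S2 (hand) and S3 (forearm), and
    extract the relative wrist angles.

    S1 (the joint sensor at A) is reserved for event reference and cut
    detection; the joint angle itself needs only the two segment sensors.
    """
    if isinstance(session, SessionRecording):
        if rate is None:
            rate = session.streams["S2"].nominal_rate
        sync = round_robin_sync(session.streams.values(), rate=rate)
    else:
        sync = session
    hand = fuse_orientation(sync.stream("S2"), config)
    forearm = fuse_orientation(sync.stream("S3"), config)
    return relative_orientation(hand, forearm)
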