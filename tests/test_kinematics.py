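import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristkin import (
    ArmModel,
    HomogeneousTransform,
    NoiseModel,
    ValidationError,
    forward_kinematics,
    generate_reference_trial,
    relative_orientation,
    rototranslate,
    rotation_x,
    rotation_y,
    rotation_z,
    translation,
    wrist_angles,
)
from wristkin.fusion import OrientationSeries
from wristkin.synth import generate_trajectory, synthesize_imu, TrajectorySpec

angles = st.floats(min_value=-170.0, max_value=170.0)


def brute_force_pose(dx, dy, dz, tx, ty, tz):
    """Independent oracle: assemble the printed matrix layouts literally and
    multiply with plain numpy."""
    a, b, c = np.deg2rad([tx, ty, tz])
    T = np.array([[1, 0, 0, dx], [0, 1, 0, dy], [0, 0, 1, dz], [0, 0, 0, 1]], dtype=float)
    Rx = np.array(
        [[1, 0, 0, 0],
         [0, np.cos(a), -np.sin(a), 0],
         [0, np.sin(a), np.cos(a), 0],
         [0, 0, 0, 1]]
    )
    Ry = np.array(
        [[np.cos(b), 0, np.sin(b), 0],
         [0, 1, 0, 0],
         [-np.sin(b), 0, np.cos(b), 0],
         [0, 0, 0, 1]]
    )
    Rz = np.array(
        [[np.cos(c), -np.sin(c), 0, 0],
         [np.sin(c), np.cos(c), 0, 0],
         [0, 0, 1, 0],
         [0, 0, 0, 1]]
    )
    return T @ Rx @ Ry @ Rz


class TestElementaryTransforms:
    def test_zero_translation_is_identity(self):
        assert translation(0, 0, 0).allclose(HomogeneousTransform.identity())

    def test_translation_moves_origin(self):
        np.testing.assert_allclose(translation(1, 2, 3).apply([0, 0, 0]), [1, 2, 3])

    def test_translation_group_property(self):
        lhs = translation(1, -2, 0.5) @ translation(0.5, 3, -1)
        assert lhs.allclose(translation(1.5, 1, -0.5))

    def test_zero_rotation_is_identity(self):
        for rot in (rotation_x, rotation_y, rotation_z):
            assert rot(0.0).allclose(HomogeneousTransform.identity())

    def test_rotation_z_right_hand_rule(self):
        np.testing.assert_allclose(
            rotation_z(90.0).apply([1, 0, 0]), [0, 1, 0], atol=1e-12
        )

    def test_rotation_composition_adds_angles(self):
        lhs = rotation_x(30.0) @ rotation_x(25.0)
        assert lhs.allclose(rotation_x(55.0))

    def test_invalid_matrix_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0  # not orthonormal
        with pytest.raises(ValidationError):
            HomogeneousTransform(bad)
        refl = np.diag([-1.0, 1.0, 1.0, 1.0])  # determinant -1
        with pytest.raises(ValidationError):
            HomogeneousTransform(refl)


class TestRototranslate:
    def test_all_zero_is_identity(self):
        assert rototranslate(0, 0, 0, 0, 0, 0).allclose(HomogeneousTransform.identity())

    def test_pure_translation(self):
        assert rototranslate(1, 2, 3).allclose(translation(1, 2, 3))

    def test_specific_pose_against_brute_force(self):
        got = rototranslate(0, 0, 0, 30, 40, 50)
        np.testing.assert_allclose(got.matrix, brute_force_pose(0, 0, 0, 30, 40, 50), atol=1e-12)
        np.testing.assert_allclose(
            got.apply([0, 0, 1]), brute_force_pose(0, 0, 0, 30, 40, 50)[:3, 2], atol=1e-12
        )

    def test_oracle_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(20240902)
        for _ in range(1000):
            d = rng.uniform(-1, 1, 3)
            th = rng.uniform(-180, 180, 3)
            got = rototranslate(*d, *th)  # construction asserts orthonormality
            expected = brute_force_pose(*d, *th)
            np.testing.assert_allclose(got.matrix, expected, atol=1e-12)


class TestForwardKinematics:
    def test_rest_pose_along_y(self):
        pose = forward_kinematics(ArmModel(), (0, 0, 0))
        np.testing.assert_allclose(pose.n_point, [0, 0.18, 0], atol=1e-12)
        np.testing.assert_allclose(pose.s2_point, [0, 0.09, 0], atol=1e-12)

    def test_90_deg_yaw_preserves_length(self):
        pose = forward_kinematics(ArmModel(len_ab=0.18), (0, 0, 90.0))
        assert np.linalg.norm(pose.n_point) == pytest.approx(0.18, abs=1e-12)
        # rotation about z maps +y onto -x
        np.testing.assert_allclose(pose.n_point, [-0.18, 0, 0], atol=1e-12)

    @given(tx=angles, ty=angles, tz=angles)
    @settings(max_examples=200, deadline=None)
    def test_rigid_body_length_invariant(self, tx, ty, tz):
        model = ArmModel(len_ab=0.18, len_ac=0.26)
        pose = forward_kinematics(model, (tx, ty, tz))
        assert np.linalg.norm(pose.n_point) == pytest.approx(model.len_ab, rel=1e-12)
        assert np.linalg.norm(pose.s2_point) == pytest.approx(model.s2_offset, rel=1e-12)


class TestRelativeOrientation:
    def _series(self, euler_rows):
        euler = np.asarray(euler_rows, dtype=float)
        return OrientationSeries(t=np.arange(len(euler)) / 50.0, euler=euler)

    def test_identical_series_zero_angles(self):
        s = self._series([[10, 5, -3]] * 5)
        out = relative_orientation(s, s)
        np.testing.assert_allclose(out.euler, 0.0, atol=1e-9)

    def test_pure_hand_roll_recovered(self):
        hand = self._series([[45, 0, 0]] * 4)
        forearm = self._series([[0, 0, 0]] * 4)
        out = relative_orientation(hand, forearm)
        np.testing.assert_allclose(out.euler, np.tile([45, 0, 0], (4, 1)), atol=1e-9)

    def test_common_mode_rotation_cancels(self):
        both = self._series([[0, 25, 0]] * 4)
        out = relative_orientation(both, both)
        np.testing.assert_allclose(out.euler, 0.0, atol=1e-9)

    def test_swap_negates_rotation(self):
        from wristkin.fusion import euler_to_matrix

        hand = self._series([[30, -12, 40]] * 3)
        forearm = self._series([[5, 8, -20]] * 3)
        fwd = relative_orientation(hand, forearm)
        rev = relative_orientation(forearm, hand)
        R_fwd = euler_to_matrix(fwd.euler[0])
        R_rev = euler_to_matrix(rev.euler[0])
        np.testing.assert_allclose(R_rev, R_fwd.T, atol=1e-9)

    def test_grid_mismatch_rejected(self):
        a = self._series([[0, 0, 0]] * 4)
        b = OrientationSeries(t=np.arange(4) / 25.0, euler=np.zeros((4, 3)))
        with pytest.raises(ValidationError):
            relative_orientation(a, b)


class TestWristAngles:
    def test_static_neutral_session_near_zero(self):
        spec = TrajectorySpec(keyframes=[(0.0, (0, 0, 0)), (2.0, (0, 0, 0))])
        truth = generate_trajectory(spec)
        session = synthesize_imu(truth, noise=NoiseModel.none())
        out = wrist_angles(session)
        assert np.all(np.abs(out.euler) < 0.5)

    def test_held_60_deg_trial_recovered(self):
        session, truth = generate_reference_trial(60, "X", noise=NoiseModel.none())
        out = wrist_angles(session)
        for start, end in truth.hold_windows:
            m = (out.t >= start) & (out.t <= end)
            assert np.median(out.euler[m, 0]) == pytest.approx(60.0, abs=1.0)
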