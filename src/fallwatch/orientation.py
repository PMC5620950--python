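"""Body-orientation estimation from 9-DOF IMU data.

The attitude of a body segment is tracked as a unit quaternion and read out as
Euler angles (yaw, pitch, roll).  Tracking follows the classic two-stage
fusion scheme: the gyroscope is integrated to *predict* the next attitude, and
the accelerometer (gravity direction) and magnetometer (heading) *correct*
that prediction with small proportional rotations.  Gyro integration alone
accumulates noise and bias into an unbounded drift; gravity and heading are
drift-free observations, so a small continuous correction bounds the error.

Conventions
-----------
* The state quaternion ``q = (q_w, q_x, q_y, q_z)`` maps world-frame vectors
  into the body frame (``v_body = R(q) v_world``); the world z axis points up,
  so a level stationary accelerometer reads ``(0, 0, 1)`` g.
* The Euler readout implements the component formulas

  .. math::

     \\mathrm{yaw}   = \\mathrm{atan2}(2q_xq_y - 2q_wq_z,\\; 2q_w^2 + 2q_x^2 - 1)\\\\
     \\mathrm{pitch} = \\arcsin(2q_wq_y - 2q_xq_z)\\\\
     \\mathrm{roll}  = \\mathrm{atan2}(2q_yq_z - 2q_wq_x,\\; 2q_w^2 + 2q_z^2 - 1)

  exactly as the fall-detection literature this package models states them.
  Note that this particular triple mixes conventions: the pitch line is the
  standard Hamilton ZYX extraction while the yaw and roll lines are the
  extraction of the *conjugate* quaternion.  Taken together they are not the
  Euler decomposition of any single rotation convention and have no global
  inverse.  Each single-axis family is inverted exactly by
  :func:`euler_to_quaternion`, and in the dominant-single-axis regime of human
  falls the dominant channel reads out exactly (pitch) or nearly exactly
  (roll); see ``docs/methods.md`` for the full analysis.
* Public interfaces use degrees (detection thresholds are stated in degrees);
  radians are internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, TransformerMixin

from .imu_io import DerivedTrace, IMUStream

__all__ = [
    "Quaternion",
    "EulerAngles",
    "FusionConfig",
    "quaternion_to_euler",
    "euler_to_quaternion",
    "integrate_gyro",
    "correct_with_accel_mag",
    "initial_orientation",
    "estimate_orientation",
    "OrientationEstimator",
]


class EulerAngles(NamedTuple):
    """Yaw, pitch, roll in degrees; pitch in [-90, 90], others in (-180, 180]."""

    yaw: float
    pitch: float
    roll: float


@dataclass(frozen=True)
class Quaternion:
    """Unit quaternion ``(w, x, y, z)`` with scalar part ``w``."""

    w: float
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(q: Sequence[float]) -> "Quaternion":
        w, x, y, z = (float(v) for v in q)
        return Quaternion(w, x, y, z)

    @property
    def norm(self) -> float:
        return float(np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2))

    def normalized(self) -> "Quaternion":
        n = self.norm
        if n < 1e-12:
            raise ValueError("cannot normalize a (near-)zero quaternion")
        return Quaternion(self.w / n, self.x / n, self.y / n, self.z / n)


# ---------------------------------------------------------------------------
# low-level quaternion algebra on (w, x, y, z) ndarrays
# ---------------------------------------------------------------------------


def _as_quat_array(q) -> np.ndarray:
    if isinstance(q, Quaternion):
        return q.as_array()
    arr = np.asarray(q, dtype=float).ravel()
    if arr.size != 4:
        raise ValueError(f"expected 4 quaternion components, got {arr.size}")
    return arr


def _qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _qconj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def _qnormalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n < 1e-12:
        raise ValueError("cannot normalize a (near-)zero quaternion")
    return q / n

def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """exp map: rotation vector (radians, axis*angle) -> unit quaternion."""
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
    axis = v / angle
    half = 0.5 * angle
    s = np.sin(half)
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def _rotvec_from_quat(q: np.ndarray) -> np.ndarray:
    """log map: unit quaternion -> rotation vector (radians)."""
    q = _qnormalize(q)
    if q[0] < 0:
        q = -q
    vec = q[1:]
    s = np.linalg.norm(vec)
    if s < 1e-12:
        return 2.0 * vec
    angle = 2.0 * np.arctan2(s, q[0])
    return angle * vec / s


def _rotmat(q: np.ndarray) -> np.ndarray:
    """Hamilton rotation matrix of q; maps world vectors to body frame here."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_quat(axis: int, angle_rad: float) -> np.ndarray:
    q = np.zeros(4)
    q[0] = np.cos(angle_rad / 2.0)
    q[1 + axis] = np.sin(angle_rad / 2.0)
    return q


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def quaternion_to_euler(q) -> EulerAngles:
    """Convert a unit quaternion to Euler angles (degrees).

    The component formulas documented in the module header are evaluated
    exactly; the arcsine argument is clamped to [-1, 1] so that rounding noise
    at the gimbal boundary yields pitch of exactly +/-90 degrees.  The input
    is normalized internally; a zero quaternion raises ``ValueError``.
    """
    arr = _qnormalize(_as_quat_array(q))
    w, x, y, z = arr
    yaw = np.degrees(np.arctan2(2 * x * y - 2 * w * z, 2 * w * w + 2 * x * x - 1))
    pitch = np.degrees(np.arcsin(np.clip(2 * w * y - 2 * x * z, -1.0, 1.0)))
    roll = np.degrees(np.arctan2(2 * y * z - 2 * w * x, 2 * w * w + 2 * z * z - 1))
    # atan2 returns [-180, 180]; fold the open end so -180 maps to +180
    if yaw <= -180.0:
        yaw += 360.0
    if roll <= -180.0:
        roll += 360.0
    return EulerAngles(float(yaw), float(pitch), float(roll))


def euler_to_quaternion(yaw: float, pitch: float, roll: float) -> Quaternion:
    """Build the attitude quaternion realising the given Euler angles (degrees).

    The composition ``q = q_z(-yaw) * q_y(pitch) * q_x(-roll)`` is used; each
    factor alone is inverted exactly by :func:`quaternion_to_euler`, and the
    pitch channel is recovered exactly for arbitrary mixed angles.  Because
    the readout formula has no global inverse (see module docstring), the yaw
    and roll channels of a *mixed* large-angle rotation are recovered only
    approximately; the error is second order in the secondary angles.
    """
    y, p, r = np.radians([yaw, pitch, roll])
    q = _qmul(_qmul(_axis_quat(2, -y), _axis_quat(1, p)), _axis_quat(0, -r))
    return Quaternion.from_array(q)


def integrate_gyro(q, omega_dps: Sequence[float], dt: float) -> Quaternion:
    """First-order attitude update from a body-frame angular rate (deg/s).

    Applies the quaternion kinematic equation for the world-to-body state,
    ``q <- exp(-omega * dt / 2) (x) q``, and renormalizes.  A zero rate
    returns the (normalized) input unchanged.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    arr = _qnormalize(_as_quat_array(q))
    omega = np.radians(np.asarray(omega_dps, dtype=float))
    delta = _quat_from_rotvec(-omega * dt)
    return Quaternion.from_array(_qnormalize(_qmul(delta, arr)))


@dataclass
class FusionConfig:
    """Tuning of the accel/mag corrector.

    ``accel_gain`` and ``mag_gain`` are the fractions of the observed
    gravity-direction and heading error removed per sample (unitless, in
    [0, 1]; the defaults correspond to time constants of roughly 0.5 s and
    1 s at 100 Hz).  ``gravity_ref`` is the world gravity direction in g and
    ``mag_ref`` the world magnetic field in uT (horizontal component defines
    magnetic north; the vertical component models inclination).  Samples whose
    acceleration norm is below ``freefall_threshold`` (g) skip the gravity
    correction: during the weightless start phase of a fall the gravity
    direction is unobservable.
    """

    accel_gain: float = 0.02
    mag_gain: float = 0.01
    gravity_ref: tuple[float, float, float] = (0.0, 0.0, 1.0)
    mag_ref: tuple[float, float, float] = (22.0, 0.0, -42.0)
    freefall_threshold: float = 0.3

    def __post_init__(self) -> None:
        for name in ("accel_gain", "mag_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if np.linalg.norm(self.gravity_ref) < 1e-9:
            raise ValueError("gravity_ref must be non-zero")
        if np.linalg.norm(np.asarray(self.mag_ref)[:2]) < 1e-9:
            raise ValueError("mag_ref must have a non-zero horizontal component")


def correct_with_accel_mag(
    q,
    accel: Sequence[float],
    mag: Sequence[float],
    cfg: FusionConfig | None = None,
) -> tuple[Quaternion, bool]:
    """Rotate ``q`` partially toward agreement with gravity and heading.

    The gravity step rotates the state (in the body frame) so that the
    predicted gravity direction moves toward the measured acceleration
    direction by ``accel_gain`` of the observed tilt error; it cannot change
    heading.  The heading step rotates the state about the *world* z axis by
    ``mag_gain`` of the heading error between the measured magnetic field
    (expressed in the world frame) and the reference field; it cannot change
    the gravity direction.  Returns ``(corrected, freefall_skipped)`` where
    the flag reports that the gravity step was skipped because the
    acceleration norm was below ``cfg.freefall_threshold``.
    """
    cfg = cfg or FusionConfig()
    arr = _qnormalize(_as_quat_array(q))
    accel = np.asarray(accel, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if np.linalg.norm(mag) < 1e-9:
        raise ValueError("magnetometer vector must be non-zero")

    freefall = bool(np.linalg.norm(accel) < cfg.freefall_threshold)
    if not freefall and cfg.accel_gain > 0.0:
        g_world = np.asarray(cfg.gravity_ref, dtype=float)
        g_pred = _rotmat(arr) @ (g_world / np.linalg.norm(g_world))
        a_meas = accel / np.linalg.norm(accel)
        axis = np.cross(g_pred, a_meas)
        s = np.linalg.norm(axis)
        c = float(np.dot(g_pred, a_meas))
        if s > 1e-12:
            angle = np.arctan2(s, c)
            arr = _qnormalize(
                _qmul(_quat_from_rotvec(cfg.accel_gain * angle * axis / s), arr)
            )

    if cfg.mag_gain > 0.0:
        m_ref = np.asarray(cfg.mag_ref, dtype=float)
        m_world = _rotmat(arr).T @ mag
        h_meas = np.hypot(m_world[0], m_world[1])
        if h_meas > 1e-9:
            err = np.arctan2(m_world[1], m_world[0]) - np.arctan2(m_ref[1], m_ref[0])
            err = np.arctan2(np.sin(err), np.cos(err))
            # world-frame z rotation enters on the right of the state
            arr = _qnormalize(_qmul(arr, _axis_quat(2, cfg.mag_gain * err)))

    return Quaternion.from_array(arr), freefall


def initial_orientation(
    accel: Sequence[float], mag: Sequence[float], cfg: FusionConfig | None = None
) -> Quaternion:
    """Algebraic (TRIAD-style) attitude from one accel + mag pair.

    Builds an orthonormal triad from the measured gravity and magnetic field
    directions in the body frame and the corresponding reference directions in
    the world frame, and solves for the rotation mapping one onto the other.
    Used to initialise :func:`estimate_orientation` so the first seconds of a
    trace are not corrupted by an arbitrary identity start.
    """
    cfg = cfg or FusionConfig()
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    if np.linalg.norm(a) < 1e-9 or np.linalg.norm(m) < 1e-9:
        raise ValueError("initial accel and mag vectors must be non-zero")

    def triad(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
        e1 = v1 / np.linalg.norm(v1)
        h = v2 - np.dot(v2, e1) * e1
        if np.linalg.norm(h) < 1e-9:
            raise ValueError("gravity and magnetic directions are collinear")
        e2 = h / np.linalg.norm(h)
        return np.column_stack([e1, e2, np.cross(e1, e2)])

    body = triad(a, m)
    world = triad(np.asarray(cfg.gravity_ref, float), np.asarray(cfg.mag_ref, float))
    rot = body @ world.T  # maps world vectors to body vectors
    x, y, z, w = Rotation.from_matrix(rot).as_quat()
    return Quaternion.from_array(_qnormalize(np.array([w, x, y, z])))


def estimate_orientation(
    stream: IMUStream, cfg: FusionConfig | None = None
) -> DerivedTrace:
    """Run the predict/correct fusion over a stream; one output per sample.

    The RMS channel is computed from the accelerometer alone (it is invariant
    under the fusion settings); yaw/pitch/roll come from the fused quaternion
    via :func:`quaternion_to_euler`.  The initial attitude is solved from the
    first sample's accel + mag pair.
    """
    from .detection import compute_rms

    cfg = cfg or FusionConfig()
    n = len(stream)
    if n == 0:
        raise ValueError("cannot estimate orientation of an empty stream")
    dt = 1.0 / stream.rate

    q = initial_orientation(stream.accel[0], stream.mag[0], cfg).as_array()
    yaw = np.empty(n)
    pitch = np.empty(n)
    roll = np.empty(n)
    for i in range(n):
        if i > 0:
            omega = np.radians(stream.gyro[i])
            q = _qnormalize(_qmul(_quat_from_rotvec(-omega * dt), q))
        qq, _ = correct_with_accel_mag(q, stream.accel[i], stream.mag[i], cfg)
        q = qq.as_array()
        yaw[i], pitch[i], roll[i] = quaternion_to_euler(q)

    return DerivedTrace(
        t=stream.t.copy(),
        rms=compute_rms(stream.accel),
        yaw=yaw,
        pitch=pitch,
        roll=roll,
        rate=stream.rate,
        segment=stream.segment,
    )


class OrientationEstimator(BaseEstimator, TransformerMixin):
    """Sensor-fusion attitude estimator with a scikit-learn transformer API.

    ``transform`` maps an :class:`~fallwatch.imu_io.IMUStream` (or a list of
    them) to :class:`~fallwatch.imu_io.DerivedTrace` objects.  The estimator
    is stateless across streams; ``fit`` only validates parameters and
    records the assembled :class:`FusionConfig` as ``config_``.
    """

    def __init__(
        self,
        accel_gain: float = 0.02,
        mag_gain: float = 0.01,
        gravity_ref: tuple[float, float, float] = (0.0, 0.0, 1.0),
        mag_ref: tuple[float, float, float] = (22.0, 0.0, -42.0),
        freefall_threshold: float = 0.3,
    ) -> None:
        self.accel_gain = accel_gain
        self.mag_gain = mag_gain
        self.gravity_ref = gravity_ref
        self.mag_ref = mag_ref
        self.freefall_threshold = freefall_threshold

    def fit(self, X=None, y=None) -> "OrientationEstimator":
        self.config_ = FusionConfig(
            accel_gain=self.accel_gain,
            mag_gain=self.mag_gain,
            gravity_ref=tuple(self.gravity_ref),
            mag_ref=tuple(self.mag_ref),
            freefall_threshold=self.freefall_threshold,
        )
        return self

    def transform(self, X):
        if not hasattr(self, "config_"):
            self.fit()
        if isinstance(X, IMUStream):
            return estimate_orientation(X, self.config_)
        return [estimate_orientation(s, self.config_) for s in X]
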