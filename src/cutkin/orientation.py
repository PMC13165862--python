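"""Quaternion extended Kalman filter for trunk orientation estimation.

The filter state is the unit quaternion q = (q0, q1, q2, q3) (scalar first)
describing the rotation from the sensor frame to the world frame, with a
4x4 error covariance P.  Each cycle:

* **predict** — angular velocity propagates the quaternion through
  first-order discrete kinematics, q <- normalize((I + dt/2 * Omega(w)) q),
  and the covariance through P <- F P F' + Q with F = I + dt/2 * Omega(w);
* **update** — the accelerometer reading is compared against the gravity
  vector rotated into the sensor frame, h(q) = R(q)' (0, 0, g); the Kalman
  gain K = P H' (H P H' + R)^-1 corrects the state (q <- q + K y, then
  renormalized) and the covariance is updated in the Joseph-stabilized form.

Yaw is unobservable from gravity alone (the magnetometer is deliberately
not fused), so heading relies purely on integrated angular velocity; roll
and pitch are drift-corrected.  Euler output follows the intrinsic Z-Y-X
(yaw-pitch-roll) aerospace convention, in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: gravity magnitude used as the accelerometer reference, m/s²
DEFAULT_G = 9.80655

_DEG = np.pi / 180.0

# ---------------------------------------------------------------------------
# quaternion utilities (scalar-first, unit quaternions)
# ---------------------------------------------------------------------------


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (scalar-first)."""
    a0, a1, a2, a3 = a
    b0, b1, b2, b3 = b
    return np.array(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ]
    )


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R(q) mapping sensor-frame vectors to the world frame."""
    q0, q1, q2, q3 = q
    return np.array(
        [
            [
                1 - 2 * (q2 * q2 + q3 * q3),
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                1 - 2 * (q1 * q1 + q3 * q3),
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                1 - 2 * (q1 * q1 + q2 * q2),
            ],
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle_rad
    return np.r_[np.cos(half), np.sin(half) * axis / n]


def euler_to_quat(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Intrinsic Z-Y-X Euler angles (degrees) to a unit quaternion."""
    r, p, y = roll_deg * _DEG / 2, pitch_deg * _DEG / 2, yaw_deg * _DEG / 2
    cr, sr, cp, sp, cy, sy = np.cos(r), np.sin(r), np.cos(p), np.sin(p), np.cos(y), np.sin(y)
    return np.array(
        [
            cy * cp * cr + sy * sp * sr,
            cy * cp * sr - sy * sp * cr,
            cy * sp * cr + sy * cp * sr,
            sy * cp * cr - cy * sp * sr,
        ]
    )


def quat_to_euler(q: np.ndarray) -> tuple[float, float, float]:
    """Unit quaternion to intrinsic Z-Y-X Euler angles (roll, pitch, yaw), degrees.

    Non-unit input is normalized with a warning; pitch within 0.1° of ±90°
    (gimbal proximity) is flagged in the log.
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        logger.warning("quat_to_euler received non-unit quaternion (|q|=%g)", n)
        q = q / n
    q0, q1, q2, q3 = q
    sinp = np.clip(2 * (q0 * q2 - q3 * q1), -1.0, 1.0)
    pitch = np.arcsin(sinp)
    roll = np.arctan2(2 * (q0 * q1 + q2 * q3), 1 - 2 * (q1 * q1 + q2 * q2))
    yaw = np.arctan2(2 * (q0 * q3 + q1 * q2), 1 - 2 * (q2 * q2 + q3 * q3))
    if abs(pitch) > 89.9 * _DEG:
        logger.warning("gimbal proximity: |pitch| = %.3f deg", abs(pitch) / _DEG)
    return float(roll / _DEG), float(pitch / _DEG), float(yaw / _DEG)


def omega_matrix(w: np.ndarray) -> np.ndarray:
    """4x4 skew matrix Omega(w) with quaternion kinematics qdot = 1/2 Omega q."""
    wx, wy, wz = w
    return np.array(
        [
            [0.0, -wx, -wy, -wz],
            [wx, 0.0, wz, -wy],
            [wy, -wz, 0.0, wx],
            [wz, wy, -wx, 0.0],
        ]
    )


# ---------------------------------------------------------------------------
# filter configuration and state
# ---------------------------------------------------------------------------


@dataclass
class EkfConfig:
    """Tuning parameters of the orientation EKF.

    dt is the IMU sample period (0.005 s at 200 Hz).  Q defaults to
    sigma_q² I₄ and R to sigma_a² I₃; both can be overridden with full
    matrices.  sigma_q (unitless quaternion process noise per step) and
    sigma_a (accelerometer noise, m/s²) are tuning choices validated on
    synthetic trajectories with known ground truth.
    """

    dt: float = 0.005
    g: float = DEFAULT_G
    sigma_q: float = 1e-4
    sigma_a: float = 0.5
    Q: np.ndarray | None = None
    R: np.ndarray | None = None
    static_calibration_duration: float = 0.4
    accel_min_norm: float = 1.0  # m/s²; below this the update is skipped

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.Q is None:
            self.Q = self.sigma_q**2 * np.eye(4)
        else:
            self.Q = np.asarray(self.Q, dtype=float)
        if self.R is None:
            self.R = self.sigma_a**2 * np.eye(3)
        else:
            self.R = np.asarray(self.R, dtype=float)
        for name, m in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-12:
                raise ValueError(f"{name} must be positive semidefinite")


@dataclass
class OrientationState:
    """Unit quaternion + 4x4 error covariance."""

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    P: np.ndarray = field(default_factory=lambda: 1e-2 * np.eye(4))

    def __post_init__(self) -> None:
        self.q = quat_normalize(np.asarray(self.q, dtype=float))
        self.P = np.asarray(self.P, dtype=float)


@dataclass
class EulerSeries:
    """Per-sample Euler angles (degrees) aligned with the input IMU series."""

    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    fs: float
    quaternions: np.ndarray | None = None  # (n, 4), scalar-first

    def __len__(self) -> int:
        return self.roll.size


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def calibrate_gyro_bias(
    gyro: np.ndarray,
    fs: float,
    duration: float,
    staticity_threshold: float = 2.0,
) -> np.ndarray:
    """Per-axis gyro bias (°/s) from an assumed-static window at the start.

    The bias is the per-axis mean over the first ``duration`` seconds.  A
    per-axis standard deviation above ``staticity_threshold`` °/s suggests
    the window was not static and is logged as a warning.
    """
    gyro = np.asarray(gyro, dtype=float)
    n = int(round(duration * fs))
    if n < 1 or n > gyro.shape[0]:
        raise ValueError(
            f"calibration window of {duration} s ({n} samples) exceeds the "
            f"series length {gyro.shape[0]}"
        )
    window = gyro[:n]
    sd = window.std(axis=0)
    if np.any(sd > staticity_threshold):
        logger.warning(
            "gyro calibration window may not be static (per-axis SD %s deg/s)",
            np.round(sd, 2),
        )
    return window.mean(axis=0)


def ekf_predict(
    state: OrientationState, gyro_rad: np.ndarray, cfg: EkfConfig
) -> OrientationState:
    """Propagate quaternion and covariance one step from angular velocity (rad/s)."""
    gyro_rad = np.asarray(gyro_rad, dtype=float)
    if not np.all(np.isfinite(gyro_rad)):
        raise ValueError(f"non-finite gyro sample: {gyro_rad}")
    F = np.eye(4) + 0.5 * cfg.dt * omega_matrix(gyro_rad)
    q = quat_normalize(F @ state.q)
    P = F @ state.P @ F.T + cfg.Q
    return OrientationState(q=q, P=0.5 * (P + P.T))


def _gravity_in_sensor(q: np.ndarray, g: float) -> np.ndarray:
    """h(q) = R(q)' (0, 0, g): world gravity reference seen by the accelerometer."""
    q0, q1, q2, q3 = q
    return g * np.array(
        [
            2 * (q1 * q3 - q0 * q2),
            2 * (q2 * q3 + q0 * q1),
            1 - 2 * (q1 * q1 + q2 * q2),
        ]
    )


def _measurement_jacobian(q: np.ndarray, g: float) -> np.ndarray:
    """H = dh/dq, 3x4, full quaternion linearization."""
    q0, q1, q2, q3 = q
    return 2 * g * np.array(
        [
            [-q2, q3, -q0, q1],
            [q1, q0, q3, q2],
            [0.0, -2 * q1, -2 * q2, 0.0],
        ]
    )


def ekf_update(
    state: OrientationState, accel: np.ndarray, cfg: EkfConfig
) -> OrientationState:
    """Correct the predicted state with an accelerometer gravity observation."""
    accel = np.asarray(accel, dtype=float)
    if np.linalg.norm(accel) < cfg.accel_min_norm:
        logger.warning(
            "accelerometer magnitude %.3g m/s^2 near free-fall; update skipped",
            np.linalg.norm(accel),
        )
        return state
    q, P = state.q, state.P
    h = _gravity_in_sensor(q, cfg.g)
    H = _measurement_jacobian(q, cfg.g)
    y = accel - h
    S = H @ P @ H.T + cfg.R
    try:
        K = np.linalg.solve(S.T, (P @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance (|S|={np.linalg.det(S):g})"
        ) from exc
    q_new = quat_normalize(q + K @ y)
    IKH = np.eye(4) - K @ H
    P_new = IKH @ P @ IKH.T + K @ cfg.R @ K.T  # Joseph form
    return OrientationState(q=q_new, P=0.5 * (P_new + P_new.T))


def run_ekf(
    acc: np.ndarray,
    gyro_deg: np.ndarray,
    cfg: EkfConfig | None = None,
    initial: OrientationState | None = None,
) -> EulerSeries:
    """Run the predict-update loop over a full trial.

    Parameters
    ----------
    acc : (n, 3) accelerometer, m/s² (sensor frame, gravity included).
    gyro_deg : (n, 3) bias-corrected angular velocity, °/s.
    cfg : filter configuration; defaults to :class:`EkfConfig`.
    initial : starting state; defaults to identity orientation.

    Returns an :class:`EulerSeries` aligned sample-for-sample with the input.
    """
    cfg = cfg or EkfConfig()
    acc = np.asarray(acc, dtype=float)
    gyro_rad = np.asarray(gyro_deg, dtype=float) * _DEG
    if acc.shape != gyro_rad.shape or acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("acc and gyro must both be (n, 3)")
    n = acc.shape[0]
    state = initial or OrientationState()
    quats = np.empty((n, 4))
    roll = np.empty(n)
    pitch = np.empty(n)
    yaw = np.empty(n)
    for k in range(n):
        try:
            state = ekf_predict(state, gyro_rad[k], cfg)
            state = ekf_update(state, acc[k], cfg)
        except Exception as exc:
            raise type(exc)(f"EKF failed at sample {k}: {exc}") from exc
        quats[k] = state.q
        roll[k], pitch[k], yaw[k] = quat_to_euler(state.q)
    return EulerSeries(
        roll=roll, pitch=pitch, yaw=yaw, fs=1.0 / cfg.dt, quaternions=quats
    )
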