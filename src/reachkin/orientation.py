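"""Sensor orientation from gyro + accel, and gravity-free earth-frame accel.

Implements the gradient-descent complementary AHRS filter of Madgwick in
its IMU-only (no magnetometer) form. Heading is unobservable without a
magnetometer, but every downstream quantity is a resultant magnitude, so
heading drift is irrelevant; only tilt must be right for gravity removal.

Quaternion convention: q = (w, x, y, z), unit norm, rotating sensor-frame
vectors into the earth frame, v_e = q (x) v_s (x) q*.  Earth z points up,
so a stationary pronated sensor measures specific force (0, 0, +1) g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .types import GRAVITY, ImuTrial


@dataclass
class QuaternionSeries:
    """Per-sample orientation estimate (sensor-to-earth unit quaternions)."""

    q: np.ndarray  # (n, 4) as (w, x, y, z)
    beta: float

    def __len__(self) -> int:
        return len(self.q)


def _quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array([
        pw * qw - px * qx - py * qy - pz * qz,
        pw * qx + px * qw + py * qz - pz * qy,
        pw * qy - px * qz + py * qw + pz * qx,
        pw * qz + px * qy - py * qx + pz * qw,
    ])


def _rot_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with v_e = R v_s."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def initial_orientation(acc_mean: np.ndarray) -> np.ndarray:
    """Tilt-only quaternion aligning a measured gravity direction with +z.

    `acc_mean` is the mean accelerometer vector (any units) over a
    stationary window; the returned q maps it onto the earth z-axis.
    Heading is left at zero (unobservable from gravity alone).
    """
    a = np.asarray(acc_mean, dtype=np.float64)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("zero-norm accelerometer mean; cannot initialize tilt")
    a = a / norm
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(a, ez))
    axis = np.cross(a, ez)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antiparallel: 180 deg about x
        return np.array([0.0, 1.0, 0.0, 0.0])
    axis = axis / s
    half = 0.5 * np.arctan2(s, c)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def ahrs_filter(trial: ImuTrial, beta: float = 0.1,
                q0: np.ndarray | None = None,
                init_window_frames: int = 100,
                accel_reject_g: float = 0.1,
                gyro_gate_dps: float = 10.0,
                accel_dyn_gate_g: float = 0.04) -> QuaternionSeries:
    """Per-sample orientation via gyro integration + accel gradient descent.

    The quaternion rate from the gyroscope is corrected by a gradient-descent
    step toward the orientation whose predicted gravity direction matches the
    normalized accelerometer sample, scaled by `beta` (rad/s). The correction
    is rejected during dynamic phases, when the accelerometer does not point
    along gravity and following it would tilt the estimate and leak gravity
    into the linear acceleration: a sample is dynamic when its magnitude
    departs from 1 g by more than `accel_reject_g` *or* its zero-phase
    smoothed angular speed exceeds `gyro_gate_dps` (a horizontal reach
    barely changes the magnitude, so the magnitude test alone cannot gate
    it; wrist transport always rotates the forearm). Either gate can be
    disabled by passing 0. A zero-norm accelerometer sample likewise skips
    the correction. When `q0` is not given, tilt is initialized from the
    mean accelerometer vector over the first `init_window_frames` samples
    (the protocol retains a stationary lead-in, so this window is at rest).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    n = len(trial)
    if n == 0:
        raise ValueError("empty trial")
    if q0 is None:
        win = min(max(init_window_frames, 1), n)
        q = initial_orientation(trial.acc[:win].mean(axis=0))
    else:
        q = np.asarray(q0, dtype=np.float64)
        q = q / np.linalg.norm(q)

    quiet = np.ones(n, dtype=bool)
    if n > 30:
        from scipy import signal as _signal
        rate = 1.0 / np.median(np.diff(trial.t)) if n > 1 else 100.0
        nyq = rate / 2.0
        sos_lp = _signal.butter(2, min(2.0 / nyq, 0.99), btype="lowpass",
                                output="sos")
        if gyro_gate_dps > 0:
            gyro_env = _signal.sosfiltfilt(sos_lp, trial.gyro_speed)
            quiet &= gyro_env < gyro_gate_dps
        if accel_dyn_gate_g > 0:
            # band-passed acceleration energy: sees the sustained 0.5-2 Hz
            # accelerations of a reach even when they are horizontal and
            # leave the magnitude near 1 g; white sensor noise contributes
            # little power in this narrow band
            sos_bp = _signal.butter(
                2, [min(0.2 / nyq, 0.5), min(3.0 / nyq, 0.9)],
                btype="bandpass", output="sos")
            band = _signal.sosfiltfilt(sos_bp, trial.acc, axis=0)
            dyn = _signal.sosfiltfilt(sos_lp, np.linalg.norm(band, axis=1))
            thresh = max(accel_dyn_gate_g, float(np.median(dyn)) + 0.03)
            quiet &= dyn < thresh

    gyr_rad = np.deg2rad(trial.gyr)
    out = np.empty((n, 4))
    out[0] = q
    for i in range(1, n):
        dt = trial.t[i] - trial.t[i - 1]
        omega = gyr_rad[i]
        qdot = 0.5 * _quat_multiply(q, np.array([0.0, *omega]))

        a = trial.acc[i]
        anorm = np.linalg.norm(a)
        if anorm > 0 and beta > 0 and quiet[i] and (
                accel_reject_g <= 0 or abs(anorm - 1.0) < accel_reject_g):
            ax, ay, az = a / anorm
            w, x, y, z = q
            # objective: predicted gravity direction in the sensor frame
            # (R^T e_z) minus the normalized accel measurement
            f1 = 2 * (x * z - w * y) - ax
            f2 = 2 * (y * z + w * x) - ay
            f3 = (w * w - x * x - y * y + z * z) - az
            grad = np.array([
                -2 * y * f1 + 2 * x * f2 + 2 * w * f3,
                2 * z * f1 + 2 * w * f2 - 2 * x * f3,
                -2 * w * f1 + 2 * z * f2 - 2 * y * f3,
                2 * x * f1 + 2 * y * f2 + 2 * z * f3,
            ])
            gnorm = np.linalg.norm(grad)
            if gnorm > 0:
                qdot = qdot - beta * grad / gnorm

        q = q + qdot * dt
        q = q / np.linalg.norm(q)
        out[i] = q
    return QuaternionSeries(q=out, beta=beta)


def to_earth_frame(trial: ImuTrial, qs: QuaternionSeries) -> np.ndarray:
    """Earth-frame linear acceleration (m/s^2) with gravity removed.

    Rotates each accelerometer sample into the earth frame, subtracts 1 g
    from the (post-rotation) z-axis and converts to m/s^2.
    """
    if len(qs) != len(trial):
        raise AlignmentError(
            f"quaternion series length {len(qs)} != trial length {len(trial)}")
    a_e = np.empty((len(trial), 3))
    for i in range(len(trial)):
        a_e[i] = _rot_matrix(qs.q[i]) @ trial.acc[i]
    a_e[:, 2] -= 1.0
    return a_e * GRAVITY
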