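"""Unit quaternions and Mahony complementary attitude estimation.

Conventions
-----------
Quaternions are stored ``[w, x, y, z]`` and represent the orientation of
the sensor frame with respect to the world frame: ``R(q)`` maps sensor
coordinates to world coordinates.  The world vertical is the +X axis
(matching the anatomical convention used throughout the package, where
the segment X axis points head-ward), so a resting accelerometer that
measures the gravity reaction reads ``R(q)^T @ (g, 0, 0)``.

The Mahony filter corrects gyroscope integration with the cross product
between the measured and predicted gravity directions, scaled by a
proportional gain (and an optional integral gain for bias tracking).
Magnetometers are deliberately unsupported: heading is unobservable and
is removed downstream by zeroing all frames at the standing snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "quat_multiply",
    "quat_conjugate",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_from_axis_angle",
    "quat_from_accel",
    "MahonyFilter",
    "mahony_update",
    "WORLD_UP",
]

WORLD_UP = np.array([1.0, 0.0, 0.0])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping sensor coordinates to world coordinates."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Shepperd's method; returns a unit quaternion with w >= 0."""
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_from_accel(accel: np.ndarray, up: np.ndarray = WORLD_UP) -> np.ndarray:
    """Tilt-only initial attitude from a static accelerometer sample.

    Returns the minimal rotation (zero heading) aligning the measured
    gravity reaction with the world vertical; used to initialize the
    filter from the standing phase.
    """
    a = np.asarray(accel, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("zero-norm accelerometer sample")
    a = a / n
    # q maps sensor->world, so we need R(q) @ a == up
    v = np.cross(a, up)
    c = float(np.dot(a, up))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antiparallel: rotate 180 deg about any axis orthogonal to `up`
        ortho = np.array([0.0, 1.0, 0.0]) if abs(up[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        return quat_from_axis_angle(np.cross(up, ortho), np.pi)
    angle = np.arctan2(np.linalg.norm(v), c)
    return quat_from_axis_angle(v, angle)


def mahony_update(
    q: np.ndarray,
    gyro: np.ndarray,
    accel: np.ndarray,
    dt: float,
    kp: float = 0.5,
    ki: float = 0.0,
    integral: np.ndarray | None = None,
    up: np.ndarray = WORLD_UP,
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit-complementary-filter step.

    Parameters are the current attitude ``q`` (sensor->world), the rate
    gyro sample in rad/s, the accelerometer sample (any scale; only its
    direction is used), and the step ``dt`` in seconds.  Returns the
    updated unit quaternion and the integral error state.

    A zero-norm accelerometer sample disables the gravity correction for
    this step (pure gyro integration).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = np.asarray(q, dtype=float)
    integral = np.zeros(3) if integral is None else integral
    omega = np.asarray(gyro, dtype=float)
    a = np.asarray(accel, dtype=float)
    norm_a = np.linalg.norm(a)
    if norm_a > 0 and kp > 0:
        v_pred = quat_to_matrix(q).T @ up  # predicted gravity direction, sensor frame
        err = np.cross(a / norm_a, v_pred)
        if ki > 0:
            integral = integral + err * dt
        omega = omega + kp * err + ki * integral
    dq = 0.5 * quat_multiply(q, np.concatenate([[0.0], omega]))
    q_new = q + dq * dt
    q_new = q_new / np.linalg.norm(q_new)
    return q_new, integral


@dataclass
class MahonyFilter:
    """Stateful wrapper around :func:`mahony_update`."""

    kp: float = 0.5
    ki: float = 0.0
    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    integral: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def initialize_from_accel(self, accel: np.ndarray) -> None:
        self.q = quat_from_accel(accel)
        self.integral = np.zeros(3)

    def update(self, gyro: np.ndarray, accel: np.ndarray, dt: float) -> np.ndarray:
        self.q, self.integral = mahony_update(
            self.q, gyro, accel, dt, self.kp, self.ki, self.integral
        )
        return self.q

    def run(self, gyro: np.ndarray, accel: np.ndarray, dt: float) -> np.ndarray:
        """Filter whole streams; returns an (n, 4) quaternion trace."""
        gyro = np.asarray(gyro, dtype=float)
        accel = np.asarray(accel, dtype=float)
        out = np.empty((len(gyro), 4))
        for i in range(len(gyro)):
            out[i] = self.update(gyro[i], accel[i], dt)
        return out
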