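"""Quaternion attitude propagation from gyroscope rates.

Without a magnetometer the sensor orientation can only be tracked relative to
its initial (static) frame, by integrating the quaternion kinematic equation

    dq/dt = 1/2 * q (x) (0, wx, wy, wz)

with the body rates from the gyroscope.  The update is the additive first
order step q_k = q_{k-1} + dq/dt * dt followed by renormalisation after every
step, which keeps the quaternion on the unit sphere and avoids scaling of
rotated vectors.  Accelerations are rotated into the initial frame through
the sandwich product q (x) (0, a) (x) q*.

Conventions: Hamilton product, scalar-first component order, right-handed
axes.  All rates are rad/s.
"""

from __future__ import annotations

import numpy as np

from .io import ImuStream

#: identity rotation, scalar-first
IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-6  # contract tolerance on |q| for rotations


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a (x) b, scalar-first; broadcasts over leading axes.

    Follows i^2 = j^2 = k^2 = ijk = -1 with right-handed composition, so the
    product of two unit quaternions is the composed rotation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise FloatingPointError("cannot normalize a zero quaternion")
    return q / n


def quat_from_axis_angle(axis, angle: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` rad about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix R such that R v == rotate_by_quaternion(q, v)."""
    w, x, y, z = np.asarray(q, dtype=float)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rate_quaternion(omega) -> np.ndarray:
    """Pure quaternion (0, wx, wy, wz) holding a body rate vector, rad/s."""
    omega = np.asarray(omega, dtype=float)
    zeros = np.zeros(omega.shape[:-1] + (1,))
    return np.concatenate([zeros, omega], axis=-1)


def update_attitude(prev: np.ndarray, omega, dt: float) -> np.ndarray:
    """One first-order attitude step from body rates.

    ``q = prev + 0.5 * (prev (x) (0, omega)) * dt``, renormalised.  For zero
    rates the input is returned unchanged.  ``omega`` in rad/s, ``dt`` in s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    prev = np.asarray(prev, dtype=float)
    q = prev + 0.5 * quat_multiply(prev, rate_quaternion(omega)) * dt
    return quat_normalize(q)


def rotate_by_quaternion(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q``.

    Returns the vector part of q (x) (0, v) (x) q*; an isometry, so vector
    norms are preserved.  Raises if ``q`` is not unit within 1e-6.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError("rotate_by_quaternion requires a unit quaternion")
    out = quat_multiply(quat_multiply(q, rate_quaternion(v)),
                        quat_conjugate(q))
    return out[..., 1:]


def transform_stream(stream: ImuStream) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a calibrated stream's accelerations into the initial frame.

    Chains :func:`update_attitude` from the identity quaternion (the first
    sample defines the initial frame) and rotates each specific-force sample
    by the attitude at that instant.  Each step uses the average of the two
    rate samples bounding it — the same averaged-sample rule the velocity
    integration uses — which centers the step and removes the half-sample
    attitude lag a pure endpoint rule would carry into fast swings.

    Returns
    -------
    accel_initial : (n, 3) array
        Specific force expressed in the initial sensor frame, m/s^2.
    quats : (n, 4) array
        Per-sample sensor-to-initial attitude, scalar-first unit quaternions.
    """
    n = len(stream)
    quats = np.empty((n, 4))
    if n == 0:
        return np.empty((0, 3)), quats
    quats[0] = IDENTITY_QUAT
    for k in range(1, n):
        omega = 0.5 * (stream.gyro[k] + stream.gyro[k - 1])
        quats[k] = update_attitude(quats[k - 1], omega, stream.dt)
    accel_initial = rotate_by_quaternion(quats, stream.accel)
    return accel_initial, quats
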