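"""Minimal unit-quaternion algebra on scalar-first (w, x, y, z) arrays.

All rotation quaternions here map *sensor/head* coordinates into *earth*
coordinates: ``v_earth = R(q) @ v_head``.  The conjugate therefore carries
earth-frame vectors (e.g. the vertical) into head coordinates.

Only the handful of operations needed by the orientation filter and the
synthetic generator are implemented; anything batch-oriented delegates to
:mod:`scipy.spatial.transform`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "qmult",
    "qconj",
    "qnormalize",
    "qexp",
    "qlog",
    "qrotate",
    "from_two_vectors",
    "rotmats",
    "integrate_body_rates",
]


def qmult(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b, scalar-first, broadcasting over leading axes."""
    aw, ax, ay, az = np.moveaxis(np.asarray(a, dtype=float), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.asarray(b, dtype=float), -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def qexp(rotvec: np.ndarray) -> np.ndarray:
    """Quaternion exponential of a rotation vector (radians, axis*angle)."""
    rv = np.asarray(rotvec, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sinc form is stable at angle -> 0
    k = 0.5 * np.sinc(half / np.pi)
    out = np.empty(rv.shape[:-1] + (4,))
    out[..., 0] = np.squeeze(np.cos(half), axis=-1)
    out[..., 1:] = rv * k
    return out


def qlog(q: np.ndarray) -> np.ndarray:
    """Rotation vector (radians) of a unit quaternion; inverse of :func:`qexp`."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    q = q * sign  # shortest representation
    vnorm = np.linalg.norm(q[..., 1:], axis=-1, keepdims=True)
    angle = 2.0 * np.arctan2(vnorm, q[..., :1])
    scale = np.where(vnorm > 1e-300, angle / np.where(vnorm == 0, 1.0, vnorm), 2.0)
    return q[..., 1:] * scale


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q (i.e. apply R(q))."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return qmult(qmult(q, qv), qconj(q))[..., 1:]


def from_two_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest-arc unit quaternion rotating direction a onto direction b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:
        # antipodal: pick any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return np.concatenate([[0.0], axis])
    axis = np.cross(a, b)
    q = np.concatenate([[1.0 + c], axis])
    return q / np.linalg.norm(q)


def rotmats(q: np.ndarray) -> np.ndarray:
    """Stack of rotation matrices for scalar-first quaternions (n, 4) -> (n, 3, 3)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    return Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()


def integrate_body_rates(omega_rad: np.ndarray, dt: float, q0: np.ndarray) -> np.ndarray:
    """Integrate body-frame angular velocity into an orientation series.

    Piecewise-constant convention: ``q[k+1] = q[k] ⊗ exp(omega[k] * dt)`` with
    omega expressed in body (head) coordinates, rad/s.  The forward one-step
    quaternion log is then the exact inverse of this integration.
    """
    from ._kernels import _integrate_core

    omega_rad = np.ascontiguousarray(omega_rad, dtype=float)
    return _integrate_core(omega_rad, float(dt), np.asarray(q0, dtype=float))
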