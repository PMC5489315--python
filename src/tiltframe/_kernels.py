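"""Sequential quaternion kernels, numba-compiled when available.

The orientation filter and the ground-truth integrator are inherently
sequential (each step depends on the previous quaternion); compiled loops
keep 10-minute sessions tractable.  The numpy fallbacks are bit-compatible.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _integrate_core(omega_rad: np.ndarray, dt: float, q0: np.ndarray) -> np.ndarray:
    n = omega_rad.shape[0]
    out = np.empty((n, 4))
    qw, qx, qy, qz = q0[0], q0[1], q0[2], q0[3]
    norm = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
    qw, qx, qy, qz = qw / norm, qx / norm, qy / norm, qz / norm
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = qw, qx, qy, qz
    for k in range(n - 1):
        rx = omega_rad[k, 0] * dt
        ry = omega_rad[k, 1] * dt
        rz = omega_rad[k, 2] * dt
        angle = np.sqrt(rx * rx + ry * ry + rz * rz)
        half = 0.5 * angle
        if angle > 1e-12:
            s = np.sin(half) / angle
        else:
            s = 0.5
        bw, bx, by, bz = np.cos(half), rx * s, ry * s, rz * s
        # q = q ⊗ b
        nw = qw * bw - qx * bx - qy * by - qz * bz
        nx = qw * bx + qx * bw + qy * bz - qz * by
        ny = qw * by - qx * bz + qy * bw + qz * bx
        nz = qw * bz + qx * by - qy * bx + qz * bw
        norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
        qw, qx, qy, qz = nw / norm, nx / norm, ny / norm, nz / norm
        out[k + 1, 0], out[k + 1, 1], out[k + 1, 2], out[k + 1, 3] = qw, qx, qy, qz
    return out


@njit(cache=True)
def _filter_core(
    omega_rad: np.ndarray,
    acc: np.ndarray,
    dt: float,
    gain: float,
    q0: np.ndarray,
) -> np.ndarray:
    n = omega_rad.shape[0]
    out = np.empty((n, 4))
    qw, qx, qy, qz = q0[0], q0[1], q0[2], q0[3]
    norm = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
    qw, qx, qy, qz = qw / norm, qx / norm, qy / norm, qz / norm
    for k in range(n):
        if k > 0:
            rx = omega_rad[k - 1, 0] * dt
            ry = omega_rad[k - 1, 1] * dt
            rz = omega_rad[k - 1, 2] * dt
            angle = np.sqrt(rx * rx + ry * ry + rz * rz)
            half = 0.5 * angle
            if angle > 1e-12:
                s = np.sin(half) / angle
            else:
                s = 0.5
            bw, bx, by, bz = np.cos(half), rx * s, ry * s, rz * s
            nw = qw * bw - qx * bx - qy * by - qz * bz
            nx = qw * bx + qx * bw + qy * bz - qz * by
            ny = qw * by - qx * bz + qy * bw + qz * bx
            nz = qw * bz + qx * by - qy * bx + qz * bw
            norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
            qw, qx, qy, qz = nw / norm, nx / norm, ny / norm, nz / norm
        if gain > 0.0:
            ax_, ay_, az_ = acc[k, 0], acc[k, 1], acc[k, 2]
            anorm = np.sqrt(ax_ * ax_ + ay_ * ay_ + az_ * az_)
            if anorm > 1e-9:
                mx, my, mz = ax_ / anorm, ay_ / anorm, az_ / anorm
                # predicted gravity direction: R(q)^T e_z
                px = 2.0 * (qx * qz - qw * qy)
                py = 2.0 * (qy * qz + qw * qx)
                pz = 1.0 - 2.0 * (qx * qx + qy * qy)
                # axis = p × m
                cx = py * mz - pz * my
                cy = pz * mx - px * mz
                cz = px * my - py * mx
                s_ = np.sqrt(cx * cx + cy * cy + cz * cz)
                c_ = px * mx + py * my + pz * mz
                if s_ > 1e-12:
                    theta = np.arctan2(s_, c_)
                    a2 = -gain * theta * 0.5
                    sa = np.sin(a2) / s_
                    bw, bx, by, bz = np.cos(a2), cx * sa, cy * sa, cz * sa
                    nw = qw * bw - qx * bx - qy * by - qz * bz
                    nx = qw * bx + qx * bw + qy * bz - qz * by
                    ny = qw * by - qx * bz + qy * bw + qz * bx
                    nz = qw * bz + qx * by - qy * bx + qz * bw
                    norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
                    qw, qx, qy, qz = nw / norm, nx / norm, ny / norm, nz / norm
        out[k, 0], out[k, 1], out[k, 2], out[k, 3] = qw, qx, qy, qz
    return out
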