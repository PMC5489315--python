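"""Orientation estimation and gravity decomposition of head-mounted IMU signals.

Conventions
-----------
Head frame: x naso-occipital (forward), y interaural (leftward), z dorsal,
right-handed.  Orientation quaternions map head coordinates to earth
coordinates, scalar-first.  An upright head reads a gravity reaction of
``(0, 0, +1)`` g on the accelerometer.  Angular velocity is stored in °/s
and converted to rad/s only inside physics formulas.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal

from . import quaternions as qt

GRAVITY = 9.81  # m/s^2 per g
EARTH_UP = np.array([0.0, 0.0, 1.0])

__all__ = [
    "GRAVITY",
    "KinematicSeries",
    "OrientationSeries",
    "DerivedKinematics",
    "SpectralSummary",
    "estimate_orientation",
    "decompose_acceleration",
    "rotate_to_earth_frame",
    "band_power_fractions",
    "rotation_induced_accelerations",
    "kinematic_derivatives",
]


@dataclasses.dataclass
class KinematicSeries:
    """Synchronized head-frame angular velocity (°/s) and acceleration (g)."""

    t: np.ndarray          # (n,) seconds, uniform
    omega: np.ndarray      # (n, 3) °/s
    acc: np.ndarray        # (n, 3) g
    sample_rate: float     # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise ValueError("empty or non-1D timestamp array")
        if self.omega.shape != (len(self.t), 3) or self.acc.shape != (len(self.t), 3):
            raise ValueError("omega/acc must be (n, 3) arrays matching t")
        if not (np.isfinite(self.omega).all() and np.isfinite(self.acc).all()):
            raise ValueError("non-finite kinematic values")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if dt.min() <= 0 or np.abs(dt - dt.mean()).max() > 1e-4 / self.sample_rate:
                raise ValueError("timestamps must be strictly increasing and uniform")
            if abs(dt.mean() * self.sample_rate - 1.0) > 1e-3:
                raise ValueError("sample_rate inconsistent with timestamps")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclasses.dataclass
class OrientationSeries:
    """Estimated head-to-earth rotation with the induced gravity decomposition."""

    q_es: np.ndarray          # (n, 4) unit quaternions, scalar-first
    gravity_head: np.ndarray  # (n, 3) g, unit norm
    nongrav_head: np.ndarray  # (n, 3) g; acc = gravity_head + nongrav_head

    @property
    def n(self) -> int:
        return len(self.q_es)


@dataclasses.dataclass
class DerivedKinematics:
    omega_dot: np.ndarray     # (n, 3) °/s²
    gravity_jerk: np.ndarray  # (n, 3) g/s
    omega_earth: np.ndarray   # (n, 3) °/s


@dataclasses.dataclass
class SpectralSummary:
    frequencies: np.ndarray
    psd: dict                  # channel name -> (nfreq,) PSD summed over axes
    band_fractions: "pd.DataFrame | object"
    bands: list


def _tilt_only_quaternion(acc_dir: np.ndarray) -> np.ndarray:
    """Zero-heading quaternion whose conjugate maps earth-up onto acc_dir."""
    return qt.from_two_vectors(acc_dir, EARTH_UP)


def estimate_orientation(
    kin: KinematicSeries,
    correction_gain: float = 0.01,
    q0: "np.ndarray | str" = "from-first-sample",
) -> OrientationSeries:
    """Complementary orientation filter.

    Per step the quaternion is propagated by exact integration of the gyro
    increment, then tilted toward the accelerometer-measured gravity
    direction by a fraction ``correction_gain`` of the full correction angle
    (spherical interpolation).  ``correction_gain=0`` is pure gyro
    integration; ``correction_gain=1`` snaps the estimated gravity direction
    onto the normalized accelerometer vector.
    """
    if not 0.0 <= correction_gain <= 1.0:
        raise ValueError("correction_gain must lie in [0, 1]")
    n = kin.n
    if n == 0:
        raise ValueError("zero-length input")
    dt = kin.dt
    omega_rad = np.deg2rad(kin.omega)
    acc = kin.acc
    acc_norm = np.linalg.norm(acc, axis=1)

    if isinstance(q0, str):
        if q0 != "from-first-sample":
            raise ValueError(f"unknown q0 spec {q0!r}")
        a0 = acc[0] / acc_norm[0] if acc_norm[0] > 0 else EARTH_UP
        q = _tilt_only_quaternion(a0)
    else:
        q = qt.qnormalize(np.asarray(q0, dtype=float))

    from ._kernels import _filter_core

    qs = _filter_core(
        np.ascontiguousarray(omega_rad), np.ascontiguousarray(acc),
        dt, float(correction_gain), np.asarray(q, dtype=float),
    )

    gravity_head = qt.qrotate(qt.qconj(qs), np.broadcast_to(EARTH_UP, (n, 3)))
    gravity_head /= np.linalg.norm(gravity_head, axis=1, keepdims=True)
    nongrav = acc - gravity_head
    return OrientationSeries(q_es=qs, gravity_head=gravity_head, nongrav_head=nongrav)


def decompose_acceleration(
    kin: KinematicSeries, orient: OrientationSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Split measured acceleration into gravitational and non-gravitational parts."""
    if orient.n != kin.n:
        raise ValueError("orientation and kinematics length mismatch")
    a_g = orient.gravity_head
    return a_g, kin.acc - a_g


def rotate_to_earth_frame(vec: np.ndarray, orient: OrientationSeries) -> np.ndarray:
    """Re-express a head-frame vector series in earth coordinates, per sample."""
    vec = np.asarray(vec, dtype=float)
    if len(vec) != orient.n:
        raise ValueError("series and orientation length mismatch")
    norms = np.linalg.norm(orient.q_es, axis=1)
    if np.abs(norms - 1.0).max() > 1e-6:
        raise ValueError("orientation quaternions are not unit norm")
    return np.einsum("nij,nj->ni", qt.rotmats(orient.q_es), vec)


def band_power_fractions(
    kin: KinematicSeries,
    orient: OrientationSeries,
    bands: Sequence[tuple[float, float]] = ((0.0, 2.0), (2.0, 20.0)),
    nperseg_seconds: float = 8.0,
) -> SpectralSummary:
    """Welch spectra of acc / A^G / A^nG and per-band power fractions.

    Fractions are the band-integrated power of each component divided by the
    band-integrated power of the measured acceleration (axes summed); the
    gravitational and non-gravitational fractions do not sum exactly to one —
    the remainder is the cross-spectral term, reported in column ``cross``.
    """
    import pandas as pd

    fs = kin.sample_rate
    if kin.n < 2 * fs:
        raise ValueError("need at least 2 s of data")
    for lo, hi in bands:
        if hi > fs / 2 + 1e-9:
            raise ValueError(f"band ({lo}, {hi}) exceeds Nyquist {fs / 2}")
    nperseg = min(kin.n, int(nperseg_seconds * fs))
    comps = {
        "acc": kin.acc,
        "gravitational": orient.gravity_head,
        "nongravitational": orient.nongrav_head,
    }
    psd = {}
    freqs = None
    for name, arr in comps.items():
        f, p = signal.welch(arr, fs=fs, nperseg=nperseg, axis=0, detrend="constant")
        freqs = f
        psd[name] = p.sum(axis=1)

    rows = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi)
        total = psd["acc"][sel].sum()
        if total <= 0:
            frac_g = frac_ng = np.nan
        else:
            frac_g = psd["gravitational"][sel].sum() / total
            frac_ng = psd["nongravitational"][sel].sum() / total
        rows.append(
            {
                "band_lo": lo,
                "band_hi": hi,
                "gravitational": frac_g,
                "nongravitational": frac_ng,
                "cross": 1.0 - frac_g - frac_ng,
                "total_power": total,
            }
        )
    return SpectralSummary(
        frequencies=freqs, psd=psd, band_fractions=pd.DataFrame(rows), bands=list(bands)
    )


def band_fraction_of_channel(
    series: np.ndarray, sample_rate: float, bands: Sequence[tuple[float, float]],
    nperseg_seconds: float = 8.0,
) -> np.ndarray:
    """Fraction of a single (possibly multi-axis) signal's power per band."""
    series = np.atleast_2d(np.asarray(series, dtype=float).T).T
    if len(series) < 2 * sample_rate:
        raise ValueError("need at least 2 s of data")
    for lo, hi in bands:
        if hi > sample_rate / 2 + 1e-9:
            raise ValueError("band exceeds Nyquist")
    nperseg = min(len(series), int(nperseg_seconds * sample_rate))
    f, p = signal.welch(series, fs=sample_rate, nperseg=nperseg, axis=0, detrend=False)
    p = p.sum(axis=1)
    total = p.sum()
    out = []
    for lo, hi in bands:
        sel = (f >= lo) & (f < hi)
        out.append(p[sel].sum() / total if total > 0 else np.nan)
    return np.asarray(out)


def rotation_induced_accelerations(
    omega: np.ndarray, lever_arm: np.ndarray, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tangential (ω̇×r) and centripetal (ω×(ω×r)) accelerations, in g.

    omega is in °/s; lever_arm in meters, from the center of rotation to the
    sensor.
    """
    lever_arm = np.asarray(lever_arm, dtype=float)
    if not np.isfinite(lever_arm).all():
        raise ValueError("lever_arm must be finite")
    w = np.deg2rad(np.asarray(omega, dtype=float))
    wdot = np.gradient(w, 1.0 / sample_rate, axis=0)
    a_lt = np.cross(wdot, lever_arm) / GRAVITY
    a_cp = np.cross(w, np.cross(w, np.broadcast_to(lever_arm, w.shape))) / GRAVITY
    return a_lt, a_cp


def kinematic_derivatives(kin: KinematicSeries, orient: OrientationSeries) -> DerivedKinematics:
    """Central-difference ω̇ (°/s²) and ȧ^G (g/s), plus earth-frame ω (°/s)."""
    if kin.n < 3:
        raise ValueError("need at least 3 samples for derivatives")
    dt = kin.dt
    omega_dot = np.gradient(kin.omega, dt, axis=0)
    gravity_jerk = np.gradient(orient.gravity_head, dt, axis=0)
    omega_earth = rotate_to_earth_frame(kin.omega, orient)
    return DerivedKinematics(
        omega_dot=omega_dot, gravity_jerk=gravity_jerk, omega_earth=omega_earth
    )
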