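"""Tilt receptive fields on the sphere, equal-area projection, stability index.

Head tilt is the direction of the gravity vector in head coordinates; rate
maps average firing over samples whose tilt falls within a fixed angular
cap around each node of a quasi-uniform sphere grid.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SphereGrid",
    "TiltRateMap",
    "StabilityIndex",
    "fibonacci_sphere",
    "tilt_rate_map",
    "lambert_project",
    "stability_index",
    "cap_members",
]


def fibonacci_sphere(n_points: int = 642) -> np.ndarray:
    """Deterministic quasi-uniform lattice of unit vectors, (n, 3)."""
    i = np.arange(n_points)
    phi = np.pi * (np.sqrt(5.0) - 1.0)  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclasses.dataclass
class SphereGrid:
    points: np.ndarray          # (m, 3) unit vectors
    cap_radius: float = 20.0    # degrees

    @classmethod
    def default(cls, n_points: int = 642, cap_radius: float = 20.0) -> "SphereGrid":
        return cls(points=fibonacci_sphere(n_points), cap_radius=cap_radius)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        norms = np.linalg.norm(self.points, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("grid points must be unit vectors")


@dataclasses.dataclass
class TiltRateMap:
    grid: SphereGrid
    mean_rate: np.ndarray       # (m,) Hz, NaN where below min occupancy
    occupancy: np.ndarray       # (m,) sample counts
    cv: float                   # CV of rates across occupied points


@dataclasses.dataclass
class StabilityIndex:
    axis: str                   # 'x' or 'y'
    sigma: float                # in [-1, 1]
    lag_range: tuple
    threshold: float


def cap_members(
    directions: np.ndarray, points: np.ndarray, cap_radius_deg: float
) -> list[np.ndarray]:
    """Sample indices within an angular cap of each sphere point.

    Angular caps on the unit sphere are chord-radius balls, so a k-d tree on
    the unit vectors gives exact membership.
    """
    chord = 2.0 * np.sin(np.deg2rad(cap_radius_deg) / 2.0)
    tree = cKDTree(directions)
    return [np.asarray(ix, dtype=np.int64) for ix in
            tree.query_ball_point(points, r=chord)]


def tilt_rate_map(
    fr: np.ndarray,
    gravity_head: np.ndarray,
    grid: Optional[SphereGrid] = None,
    min_occupancy: int = 500,
) -> TiltRateMap:
    """Mean firing rate per tilt cap, plus the across-cap rate CV."""
    if grid is None:
        grid = SphereGrid.default()
    fr = np.asarray(fr, dtype=float)
    g = np.asarray(gravity_head, dtype=float)
    norms = np.linalg.norm(g, axis=1)
    if np.abs(norms - 1.0).max() > 1e-6:
        raise ValueError("gravity_head must be unit-norm per sample")
    members = cap_members(g, grid.points, grid.cap_radius)
    m = len(grid.points)
    mean_rate = np.full(m, np.nan)
    occupancy = np.zeros(m, dtype=np.int64)
    for k, ix in enumerate(members):
        occupancy[k] = len(ix)
        if len(ix) >= min_occupancy:
            mean_rate[k] = fr[ix].mean()
    occupied = np.isfinite(mean_rate)
    if not occupied.any():
        raise ValueError("no occupied grid points: map invalid")
    rates = mean_rate[occupied]
    cv = float(rates.std() / rates.mean()) if rates.mean() > 0 else np.nan
    return TiltRateMap(grid=grid, mean_rate=mean_rate, occupancy=occupancy, cv=cv)


def _pole_basis(pole: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangent basis at the pole."""
    pole = np.asarray(pole, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, pole)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, pole)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)
    return e1, e2


def lambert_project(points: np.ndarray, pole: Sequence[float] = (0.0, 0.0, 1.0)) -> np.ndarray:
    """Lambert azimuthal equal-area projection centered on ``pole``.

    Planar radius is 2·sin(θ/2) for angular distance θ from the pole
    (equator → √2, antipode → boundary circle of radius 2); azimuth is
    preserved.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pole = np.asarray(pole, dtype=float)
    if abs(np.linalg.norm(pole) - 1.0) > 1e-9:
        raise ValueError("pole must be a unit vector")
    if np.abs(np.linalg.norm(pts, axis=1) - 1.0).max() > 1e-9:
        raise ValueError("points must be unit vectors")
    e1, e2 = _pole_basis(pole)
    c = pts @ pole
    if np.any(c < -1.0 + 1e-12):
        import warnings

        warnings.warn("antipode of pole maps to the boundary circle (radius 2)")
    u = pts @ e1
    v = pts @ e2
    s = np.hypot(u, v)
    theta = np.arctan2(s, c)
    radius = 2.0 * np.sin(theta / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s > 0, radius / s, 0.0)
    out = np.column_stack([u * scale, v * scale])
    # the antipode has no azimuth: place it deterministically on the boundary
    at_antipode = (s == 0) & (c < 0)
    out[at_antipode] = [2.0, 0.0]
    return out


def stability_index(
    fr: np.ndarray,
    omega: np.ndarray,
    gravity_head: np.ndarray,
    axis: str,
    sample_rate: float,
    lag_range: Sequence[float] = (-0.04, 0.0, 0.04),
    threshold: float = 0.25,
    min_samples: int = 1000,
) -> StabilityIndex:
    """Gain-weighted cosine between hemifield sensitivity vectors.

    Sensitivity vectors are fitted separately for samples with the chosen
    gravity component above +threshold and below −threshold, at each lag in
    ``lag_range``; σ is the mean cosine between the two vectors weighted by
    the smaller of the two gains (directions are meaningless where either
    gain vanishes).
    """
    ax = {"x": 0, "y": 1}[axis]
    g = np.asarray(gravity_head, dtype=float)[:, ax]
    fr = np.asarray(fr, dtype=float)
    omega = np.asarray(omega, dtype=float)
    pos = g > threshold
    neg = g < -threshold
    if pos.sum() < min_samples or neg.sum() < min_samples:
        return StabilityIndex(axis=axis, sigma=np.nan,
                              lag_range=tuple(lag_range), threshold=threshold)
    weights = []
    cosines = []
    for lag in lag_range:
        vecs = []
        gains = []
        for mask in (pos, neg):
            v = _masked_fit(fr, omega, mask, lag, sample_rate)
            vecs.append(v)
            gains.append(np.linalg.norm(v))
        if not all(np.isfinite(gains)) or min(gains) == 0:
            continue
        cosines.append(float(np.dot(vecs[0], vecs[1]) / (gains[0] * gains[1])))
        weights.append(min(gains))
    if not weights:
        return StabilityIndex(axis=axis, sigma=np.nan,
                              lag_range=tuple(lag_range), threshold=threshold)
    sigma = float(np.average(cosines, weights=weights))
    return StabilityIndex(axis=axis, sigma=sigma,
                          lag_range=tuple(lag_range), threshold=threshold)


def _masked_fit(
    fr: np.ndarray, omega: np.ndarray, mask: np.ndarray, lag: float, sample_rate: float
) -> np.ndarray:
    """Sensitivity components fitted on a sample subset at one lag."""
    shift = int(round(lag * sample_rate))
    n = len(fr)
    t0, t1 = max(-shift, 0), n - max(shift, 0)
    idx = np.flatnonzero(mask[t0:t1]) + t0
    if len(idx) < 10:
        return np.full(3, np.nan)
    X = np.column_stack([np.ones(len(idx)), omega[idx]])
    y = fr[idx + shift]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[1:4]
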