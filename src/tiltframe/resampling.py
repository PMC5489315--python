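"""Model-free resampling (jackknife) estimation of movement-driven firing rate.

At each query time point the estimated rate ρ is the mean instantaneous
firing rate observed at *other* time points whose inertial parameters fall
within a radius ``d`` of the query in a per-channel z-scored parameter
space, excluding reference samples closer than ``w`` seconds in time (the
exclusion applies only when query and reference are the same recording).
The squared Pearson correlation between ρ and the observed instantaneous
rate is the firing-rate predictability R².
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .spiking import instantaneous_rate

__all__ = [
    "ParameterSpace",
    "RateEstimate",
    "NullDistribution",
    "PARAMETER_SETS",
    "build_channel_matrix",
    "tune_radius",
    "NeighborEstimator",
    "estimate_rate",
    "best_lag_r2",
    "predictability_table",
    "independent_estimate_correlation",
    "shuffle_null",
    "classify_inertial_selectivity",
]

# canonical channel groupings used throughout the analysis
PARAMETER_SETS = {
    "omega": ["omega_x", "omega_y", "omega_z"],
    "acc": ["acc_x", "acc_y", "acc_z"],
    "ag": ["ag_x", "ag_y", "ag_z"],
    "ang": ["ang_x", "ang_y", "ang_z"],
    "omega+acc": ["omega_x", "omega_y", "omega_z", "acc_x", "acc_y", "acc_z"],
    "omega+ag": ["omega_x", "omega_y", "omega_z", "ag_x", "ag_y", "ag_z"],
    "omega+ang": ["omega_x", "omega_y", "omega_z", "ang_x", "ang_y", "ang_z"],
}

DEFAULT_LAG_GRID = np.round(np.arange(-0.5, 0.5001, 0.02), 10)


@dataclasses.dataclass
class ParameterSpace:
    channels: Sequence[str]
    neighbor_radius: float            # d, in normalized (z-scored) units
    exclusion_window: float = 1.0     # w, seconds
    lag: float = 0.0                  # seconds; FR at t+lag paired with params at t
    min_neighbors: int = 10
    normalization: Optional[np.ndarray] = None  # per-channel SD from reference set

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("channels must be non-empty")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")
        if self.exclusion_window < 0:
            raise ValueError("exclusion_window must be >= 0")


@dataclasses.dataclass
class RateEstimate:
    rho: np.ndarray            # Hz; NaN where < min_neighbors
    coverage: float            # fraction of query samples with a defined rho
    r2: float                  # squared Pearson vs observed FR (NaN if unavailable)
    lag: float
    provenance: str = ""


@dataclasses.dataclass
class NullDistribution:
    r_values: np.ndarray
    n_iterations: int
    seed: int


def build_channel_matrix(channels: Sequence[str], kin, orient=None) -> np.ndarray:
    """Column-stack named channels from a kinematic series (+ decomposition)."""
    cols = {}
    for i, ax in enumerate("xyz"):
        cols[f"omega_{ax}"] = kin.omega[:, i]
        cols[f"acc_{ax}"] = kin.acc[:, i]
        if orient is not None:
            cols[f"ag_{ax}"] = orient.gravity_head[:, i]
            cols[f"ang_{ax}"] = orient.nongrav_head[:, i]
    try:
        return np.column_stack([cols[c] for c in channels])
    except KeyError as e:
        raise ValueError(f"unknown or unavailable channel {e}") from None


def tune_radius(ref_scaled: np.ndarray, target_median_neighbors: int = 200,
                subsample: int = 2000, seed: int = 0) -> float:
    """Radius whose median neighbor count over the reference is ~target.

    Uses the median distance to the target-th nearest neighbor of a random
    subsample, which equals the radius at which the median ball holds the
    target count.
    """
    n = len(ref_scaled)
    k = min(target_median_neighbors + 1, n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(subsample, n), replace=False)
    tree = cKDTree(ref_scaled)
    dist, _ = tree.query(ref_scaled[idx], k=k)
    return float(np.median(dist[:, -1]))


class NeighborEstimator:
    """Reusable neighbor structure for one reference set.

    Builds the k-d tree once; ρ at different lags is then a cheap weighted
    bincount over the cached neighbor lists (neighbors do not depend on lag).
    """

    def __init__(
        self,
        ref_params: np.ndarray,
        ref_fr: np.ndarray,
        ref_t: np.ndarray,
        space: ParameterSpace,
        sample_rate: float,
        lag_bounds: tuple[float, float] = (0.0, 0.0),
        ref_mask: Optional[np.ndarray] = None,
    ):
        ref_params = np.asarray(ref_params, dtype=float)
        self.ref_fr = np.asarray(ref_fr, dtype=float)
        self.ref_t = np.asarray(ref_t, dtype=float)
        self.space = space
        self.sample_rate = sample_rate
        self.shift_min = int(round(min(lag_bounds) * sample_rate))
        self.shift_max = int(round(max(lag_bounds) * sample_rate))

        if space.normalization is None:
            scale = ref_params.std(axis=0)
        else:
            scale = np.asarray(space.normalization, dtype=float)
        scale = np.where(scale > 0, scale, 1.0)
        self.scale = scale

        # keep only reference samples whose FR index stays valid at every lag
        n = len(ref_params)
        valid = np.zeros(n, dtype=bool)
        lo = max(0, -self.shift_min)
        hi = min(n, n - self.shift_max)
        valid[lo:hi] = True
        if ref_mask is not None:
            valid &= ref_mask
        self.ref_idx = np.flatnonzero(valid)
        self.tree = cKDTree(ref_params[self.ref_idx] / scale)

    def query_neighbors(
        self, query_params: np.ndarray, query_t: np.ndarray, same_recording: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        """(flat reference indices, per-query counts) after temporal exclusion."""
        q = np.asarray(query_params, dtype=float) / self.scale
        lists = self.tree.query_ball_point(q, r=self.space.neighbor_radius)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
        flat = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists]) \
            if counts.sum() else np.empty(0, dtype=np.int64)
        flat = self.ref_idx[flat]
        if same_recording and self.space.exclusion_window >= 0:
            qt = np.repeat(np.asarray(query_t, dtype=float), counts)
            keep = np.abs(self.ref_t[flat] - qt) > self.space.exclusion_window
            owners = np.repeat(np.arange(len(counts)), counts)[keep]
            flat = flat[keep]
            counts = np.bincount(owners, minlength=len(counts))
        return flat, counts

    def rho_at_lag(self, flat: np.ndarray, counts: np.ndarray, lag: float) -> np.ndarray:
        shift = int(round(lag * self.sample_rate))
        if not self.shift_min <= shift <= self.shift_max:
            raise ValueError("lag outside the structure's lag_bounds")
        vals = self.ref_fr[flat + shift]
        owners = np.repeat(np.arange(len(counts)), counts)
        sums = np.bincount(owners, weights=vals, minlength=len(counts))
        rho = np.full(len(counts), np.nan)
        ok = counts >= self.space.min_neighbors
        rho[ok] = sums[ok] / counts[ok]
        return rho


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def estimate_rate(
    query_params: np.ndarray,
    query_t: np.ndarray,
    ref_params: np.ndarray,
    ref_fr: np.ndarray,
    ref_t: np.ndarray,
    space: ParameterSpace,
    sample_rate: float,
    same_recording: bool = True,
    query_fr: Optional[np.ndarray] = None,
    provenance: str = "",
) -> RateEstimate:
    """One-shot ρ estimate at ``space.lag`` (see module docstring)."""
    est = NeighborEstimator(
        ref_params, ref_fr, ref_t, space, sample_rate,
        lag_bounds=(space.lag, space.lag),
    )
    flat, counts = est.query_neighbors(query_params, query_t, same_recording)
    rho = est.rho_at_lag(flat, counts, space.lag)
    coverage = float(np.mean(np.isfinite(rho)))
    r2 = np.nan
    if query_fr is not None:
        r = _pearson(rho, np.asarray(query_fr, dtype=float))
        r2 = r * r if np.isfinite(r) else np.nan
    if coverage == 0:
        r2 = np.nan
    return RateEstimate(rho=rho, coverage=coverage, r2=r2, lag=space.lag,
                        provenance=provenance)


def best_lag_r2(
    params: np.ndarray,
    fr: np.ndarray,
    t: np.ndarray,
    space: ParameterSpace,
    sample_rate: float,
    lag_grid: Sequence[float] = DEFAULT_LAG_GRID,
    query_stride: int = 1,
) -> tuple[float, float, float]:
    """(max R², best lag, coverage) over a lag grid, within one recording.

    ``query_stride`` subsamples the query points (not the reference) to keep
    the neighbor search affordable; R² is unbiased under subsampling.
    """
    lag_grid = np.asarray(lag_grid, dtype=float)
    est = NeighborEstimator(params, fr, t, space, sample_rate,
                            lag_bounds=(float(lag_grid.min()), float(lag_grid.max())))
    sel = slice(None, None, query_stride)
    flat, counts = est.query_neighbors(params[sel], t[sel], same_recording=True)
    fr_q = fr[sel]
    best = (np.nan, lag_grid[0], 0.0)
    for lag in lag_grid:
        rho = est.rho_at_lag(flat, counts, lag)
        # pair rho (params at t) against FR at t+lag
        shift = int(round(lag * sample_rate))
        fr_shifted = _shift_series(fr, shift)[sel]
        r = _pearson(rho, fr_shifted)
        r2 = r * r if np.isfinite(r) else np.nan
        cov = float(np.mean(np.isfinite(rho)))
        if np.isfinite(r2) and (not np.isfinite(best[0]) or r2 > best[0]):
            best = (r2, float(lag), cov)
    return best


def _shift_series(x: np.ndarray, shift: int) -> np.ndarray:
    """x(t + shift) with NaN padding at the edges."""
    out = np.full_like(np.asarray(x, dtype=float), np.nan)
    if shift == 0:
        return np.asarray(x, dtype=float).copy()
    if shift > 0:
        out[:-shift] = x[shift:]
    else:
        out[-shift:] = x[:shift]
    return out


def predictability_table(
    fr: np.ndarray,
    t: np.ndarray,
    kin,
    orient,
    sets: Sequence[str] = tuple(PARAMETER_SETS),
    lag_grid: Sequence[float] = DEFAULT_LAG_GRID,
    target_median_neighbors: int = 200,
    exclusion_window: float = 1.0,
    min_neighbors: int = 10,
    query_stride: int = 1,
    seed: int = 0,
) -> dict:
    """Per-parameter-set best-lag R² for one unit.

    Returns {set name: {"r2", "lag", "coverage", "d"}}.
    """
    out = {}
    for name in sets:
        channels = PARAMETER_SETS[name]
        X = build_channel_matrix(channels, kin, orient)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        d = tune_radius(X / scale, target_median_neighbors, seed=seed)
        space = ParameterSpace(
            channels=channels, neighbor_radius=d,
            exclusion_window=exclusion_window, min_neighbors=min_neighbors,
            normalization=scale,
        )
        r2, lag, cov = best_lag_r2(X, fr, t, space, kin.sample_rate,
                                   lag_grid=lag_grid, query_stride=query_stride)
        out[name] = {"r2": r2, "lag": lag, "coverage": cov, "d": d}
    return out


def independent_estimate_correlation(
    params: np.ndarray,
    fr: np.ndarray,
    t: np.ndarray,
    space: ParameterSpace,
    sample_rate: float,
    block_length: float = 30.0,
    query_stride: int = 1,
) -> float:
    """Pearson R between two ρ estimates built from alternating time blocks.

    The recording is partitioned into alternating ``block_length`` blocks
    A/B; the full series is estimated once using only A-reference samples
    and once using only B-reference samples; R is computed on jointly
    covered query samples.
    """
    t = np.asarray(t, dtype=float)
    n_blocks = int(np.ceil((t[-1] - t[0]) / block_length))
    if n_blocks < 4:
        raise ValueError("need at least 4 alternating blocks")
    block_id = np.floor((t - t[0]) / block_length).astype(int) % 2
    sel = slice(None, None, query_stride)
    rhos = []
    for side in (0, 1):
        est = NeighborEstimator(
            params, fr, t, space, sample_rate,
            lag_bounds=(space.lag, space.lag),
            ref_mask=(block_id == side),
        )
        flat, counts = est.query_neighbors(params[sel], t[sel], same_recording=True)
        rhos.append(est.rho_at_lag(flat, counts, space.lag))
    return _pearson(rhos[0], rhos[1])


def shuffle_null(
    spike_times: np.ndarray,
    params: np.ndarray,
    t: np.ndarray,
    space: ParameterSpace,
    sample_rate: float,
    n_iter: int = 10,
    seed: int = 0,
    block_length: float = 30.0,
    min_offset: float = 10.0,
    query_stride: int = 1,
) -> NullDistribution:
    """Independent-estimate R under circular spike-train shifts."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    spikes = np.asarray(spike_times, dtype=float)
    t = np.asarray(t, dtype=float)
    t0, span = t[0], t[-1] - t[0]
    if span < 2 * min_offset:
        raise ValueError("recording shorter than twice the minimum shuffle offset")
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_iter):
        offset = rng.uniform(min_offset, span - min_offset)
        shifted = np.sort(((spikes - t0 + offset) % span) + t0)
        fr = instantaneous_rate(shifted, t)
        rs.append(
            independent_estimate_correlation(
                params, fr, t, space, sample_rate,
                block_length=block_length, query_stride=query_stride,
            )
        )
    return NullDistribution(r_values=np.asarray(rs), n_iterations=n_iter, seed=seed)


def classify_inertial_selectivity(r2_omega: float, r2_ag: float) -> str:
    """'omega_unit' / 'ag_unit' / 'mixed' by the eightfold-and-0.1 rule."""
    if not (np.isfinite(r2_omega) and np.isfinite(r2_ag)) or r2_omega < 0 or r2_ag < 0:
        raise ValueError("R² inputs must be finite and non-negative")
    if r2_omega >= 8.0 * r2_ag and r2_omega > 0.1:
        return "omega_unit"
    if r2_ag >= 8.0 * r2_omega and r2_ag > 0.1:
        return "ag_unit"
    return "mixed"
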