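"""Lag-dependent linear rotational sensitivity vectors and receptive fields.

A unit's rotational tuning at a given lag is the OLS fit
``FR(t + lag) = c + λ·ω(t)``; λ is the sensitivity vector, its norm the
gain (Hz per °/s, equivalently °⁻¹), its direction the preferred rotation
axis.  The optimal lag maximizes the gain over a lag grid; significance is
assessed against circularly shifted spike trains.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SensitivityVector",
    "GainLagCurve",
    "ReceptiveField2D",
    "fit_sensitivity_at_lag",
    "gain_lag_curve",
    "inertio_temporal_rf",
]

DEFAULT_LAG_GRID = np.round(np.arange(-0.5, 0.5001, 0.02), 10)


@dataclasses.dataclass
class SensitivityVector:
    components: np.ndarray     # (3,) Hz per (°/s)
    gain: float                # ‖components‖
    lag: float                 # s
    intercept: float           # Hz
    significant: bool = False


@dataclasses.dataclass
class GainLagCurve:
    lags: np.ndarray
    gains: np.ndarray
    optimal_lag: float
    shuffle_band: Optional[tuple[float, float]] = None  # (mean, sd) of shuffle max-over-lags gain
    significant: bool = False
    vectors: Optional[np.ndarray] = None  # (nlag, 3) fitted components


@dataclasses.dataclass
class ReceptiveField2D:
    value_bins: np.ndarray     # (nbin+1,) channel edges
    lags: np.ndarray           # (nlag,)
    mean_rate: np.ndarray      # (nbin, nlag) Hz, NaN below min occupancy
    occupancy: np.ndarray      # (nbin, nlag) sample counts

    def slopes(self) -> np.ndarray:
        """Rate-vs-channel slope per lag, from regressing cell means on bin centers."""
        centers = 0.5 * (self.value_bins[:-1] + self.value_bins[1:])
        out = np.full(len(self.lags), np.nan)
        for j in range(len(self.lags)):
            y = self.mean_rate[:, j]
            ok = np.isfinite(y)
            if ok.sum() >= 2:
                out[j] = np.polyfit(centers[ok], y[ok], 1)[0]
        return out


def _shift_bounds(n: int, shifts: Sequence[int]) -> tuple[int, int]:
    smax = max(max(shifts), 0)
    smin = min(min(shifts), 0)
    return -smin, n - smax


def _ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via normal equations with lstsq fallback."""
    XtX = X.T @ X
    XtY = X.T @ Y
    try:
        return np.linalg.solve(XtX, XtY)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(X, Y, rcond=None)[0]


def fit_sensitivity_at_lag(
    fr: np.ndarray, omega: np.ndarray, lag: float, sample_rate: float
) -> SensitivityVector:
    """OLS sensitivity vector at one lag (positive lag: firing follows movement)."""
    fr = np.asarray(fr, dtype=float)
    omega = np.asarray(omega, dtype=float)
    shift = int(round(lag * sample_rate))
    t0, t1 = _shift_bounds(len(fr), [shift])
    if t1 - t0 < 10:
        raise ValueError("too few samples after lag alignment")
    X = np.column_stack([np.ones(t1 - t0), omega[t0:t1]])
    y = fr[t0 + shift:t1 + shift]
    if np.linalg.matrix_rank(X[:, 1:] - X[:, 1:].mean(axis=0)) < 3:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return SensitivityVector(
            components=np.full(3, np.nan), gain=np.nan, lag=lag,
            intercept=float(beta[0]), significant=False,
        )
    beta = _ols(X, y)
    comps = beta[1:4]
    return SensitivityVector(
        components=comps, gain=float(np.linalg.norm(comps)), lag=lag,
        intercept=float(beta[0]),
    )


def _gains_over_lags(
    fr_mat: np.ndarray, omega: np.ndarray, shifts: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Gain per (lag, column of fr_mat), sharing one design window.

    fr_mat is (n, m): columns are e.g. the observed rate and shuffled rates.
    Returns gains (nlag, m) and is the workhorse for the shuffle band.
    """
    n = len(fr_mat)
    t0, t1 = _shift_bounds(n, shifts)
    X = np.column_stack([np.ones(t1 - t0), omega[t0:t1]])
    XtX = X.T @ X
    gains = np.empty((len(shifts), fr_mat.shape[1]))
    comps = np.empty((len(shifts), 3, fr_mat.shape[1]))
    for i, s in enumerate(shifts):
        Y = fr_mat[t0 + s:t1 + s]
        beta = np.linalg.solve(XtX, X.T @ Y)
        comps[i] = beta[1:4]
        gains[i] = np.linalg.norm(beta[1:4], axis=0)
    return gains, comps


def gain_lag_curve(
    fr: np.ndarray,
    omega: np.ndarray,
    sample_rate: float,
    lag_grid: Sequence[float] = DEFAULT_LAG_GRID,
    n_shuffles: int = 100,
    seed: int = 0,
    min_shuffle_offset: float = 10.0,
) -> GainLagCurve:
    """Gain vs lag with a circular-shift shuffle significance band.

    The peak is significant when its gain exceeds the shuffle mean + 2 SD of
    shuffle gains at the same lag.
    """
    fr = np.asarray(fr, dtype=float)
    omega = np.asarray(omega, dtype=float)
    lag_grid = np.asarray(lag_grid, dtype=float)
    if np.abs(lag_grid).max() > 1.0 + 1e-9:
        raise ValueError("lag grid must stay within ±1 s")
    shifts = [int(round(l * sample_rate)) for l in lag_grid]
    n = len(fr)

    cols = [fr]
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        min_off = int(round(min_shuffle_offset * sample_rate))
        min_off = min(min_off, n // 4)
        offsets = rng.integers(min_off, n - min_off, size=n_shuffles)
        cols.extend(np.roll(fr, off) for off in offsets)
    fr_mat = np.column_stack(cols)

    gains, comps = _gains_over_lags(fr_mat, omega, shifts)
    observed = gains[:, 0]
    i_opt = int(np.nanargmax(observed))
    significant = False
    band = None
    if n_shuffles > 0:
        # the observed peak is a max over lags, so compare against the
        # shuffle distribution of max-over-lags gains
        shuf_max = gains[:, 1:].max(axis=0)
        mu, sd = float(shuf_max.mean()), float(shuf_max.std())
        band = (mu, sd)
        significant = observed[i_opt] > mu + 2.0 * sd
    return GainLagCurve(
        lags=lag_grid, gains=observed, optimal_lag=float(lag_grid[i_opt]),
        shuffle_band=band, significant=significant, vectors=comps[:, :, 0],
    )


def inertio_temporal_rf(
    fr: np.ndarray,
    channel: np.ndarray,
    sample_rate: float,
    value_bins: Optional[np.ndarray] = None,
    lag_grid: Sequence[float] = DEFAULT_LAG_GRID,
    condition: Optional[np.ndarray] = None,
    n_bins: int = 20,
    min_occupancy: int = 50,
) -> ReceptiveField2D:
    """Mean FR(t+lag) per (channel-value bin, lag) cell.

    ``condition`` is a boolean mask evaluated per sample (e.g. a gravity
    hemifield predicate); an all-False condition yields an all-masked field.
    """
    fr = np.asarray(fr, dtype=float)
    channel = np.asarray(channel, dtype=float)
    lag_grid = np.asarray(lag_grid, dtype=float)
    if value_bins is None:
        lo, hi = np.percentile(channel, [1, 99])
        value_bins = np.linspace(lo, hi, n_bins + 1)
    value_bins = np.asarray(value_bins, dtype=float)
    nbin = len(value_bins) - 1
    shifts = [int(round(l * sample_rate)) for l in lag_grid]
    n = len(fr)
    t0, t1 = _shift_bounds(n, shifts)

    bin_idx = np.digitize(channel[t0:t1], value_bins) - 1
    ok = (bin_idx >= 0) & (bin_idx < nbin)
    if condition is not None:
        ok &= np.asarray(condition, dtype=bool)[t0:t1]

    mean_rate = np.full((nbin, len(shifts)), np.nan)
    occupancy = np.zeros((nbin, len(shifts)), dtype=np.int64)
    bi = bin_idx[ok]
    for j, s in enumerate(shifts):
        y = fr[t0 + s:t1 + s][ok]
        counts = np.bincount(bi, minlength=nbin)
        sums = np.bincount(bi, weights=y, minlength=nbin)
        occupancy[:, j] = counts
        good = counts >= min_occupancy
        mean_rate[good, j] = sums[good] / counts[good]
    return ReceptiveField2D(
        value_bins=value_bins, lags=lag_grid, mean_rate=mean_rate, occupancy=occupancy
    )
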