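"""Global and tilt-local linear models of firing rate, and paired statistics.

Benchmarks for the model-free estimator: 'global' OLS fits on combinations
of ω, ω̇, a^G and ȧ^G over the whole recording, and 'local' rotational fits
computed per head-tilt cell with samples assigned disjointly to their
nearest occupied tilt point.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LinearModelResult",
    "REGRESSOR_SETS",
    "global_linear_fit",
    "local_linear_r2",
    "paired_comparison",
]

# regressor blocks: ω, ω̇, a^G, ȧ^G
REGRESSOR_SETS = [
    ("omega",),
    ("omega", "omega_dot"),
    ("omega", "ag"),
    ("omega", "omega_dot", "ag"),
    ("omega", "omega_dot", "ag", "ag_dot"),
]


@dataclasses.dataclass
class LinearModelResult:
    regressor_set: tuple
    coefficients: dict            # block name -> (3,) array, plus 'intercept'
    r2: float                     # in-sample coefficient of determination
    lag: float


def _design(regressors: dict, set_: Sequence[str], t0: int, t1: int) -> np.ndarray:
    blocks = [np.ones(t1 - t0)]
    for name in set_:
        if name not in regressors:
            raise ValueError(f"regressor block {name!r} not provided")
        blocks.append(regressors[name][t0:t1])
    return np.column_stack(blocks)


def global_linear_fit(
    fr: np.ndarray,
    regressors: dict,
    set_: Sequence[str],
    lag: float,
    sample_rate: float,
) -> LinearModelResult:
    """OLS fit FR(t+lag) = intercept + Σ block·coeff over the whole recording."""
    if len(set_) == 0:
        raise ValueError("regressor set must be non-empty")
    fr = np.asarray(fr, dtype=float)
    n = len(fr)
    shift = int(round(lag * sample_rate))
    t0, t1 = max(-shift, 0), n - max(shift, 0)
    X = _design(regressors, set_, t0, t1)
    y = fr[t0 + shift:t1 + shift]
    beta, residues, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("collinear design: minimum-norm solution")
    pred = X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - pred) ** 2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    coeffs = {"intercept": float(beta[0])}
    pos = 1
    for name in set_:
        coeffs[name] = beta[pos:pos + 3]
        pos += 3
    return LinearModelResult(regressor_set=tuple(set_), coefficients=coeffs,
                             r2=max(r2, 0.0), lag=lag)


def local_linear_r2(
    fr: np.ndarray,
    omega: np.ndarray,
    gravity_head: np.ndarray,
    grid_points: np.ndarray,
    occupied: np.ndarray,
    lag: float,
    sample_rate: float,
    min_cell_samples: int = 100,
) -> tuple[float, float]:
    """Pooled in-sample r² of per-tilt-cell rotational fits.

    Samples are assigned disjointly to the nearest *occupied* tilt point;
    each cell gets its own intercept + ω fit; the pooled coefficient of
    determination is computed over all assigned samples.  Returns
    (pooled r², fraction of samples left unassigned).
    """
    fr = np.asarray(fr, dtype=float)
    omega = np.asarray(omega, dtype=float)
    g = np.asarray(gravity_head, dtype=float)
    pts = np.asarray(grid_points, dtype=float)[np.asarray(occupied, dtype=bool)]
    if len(pts) == 0:
        raise ValueError("no occupied tilt points")
    n = len(fr)
    shift = int(round(lag * sample_rate))
    t0, t1 = max(-shift, 0), n - max(shift, 0)

    # nearest occupied point by maximal dot product == minimal chord distance
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    _, cell = tree.query(g[t0:t1], k=1)

    y_all = fr[t0 + shift:t1 + shift]
    pred = np.full(t1 - t0, np.nan)
    for c in range(len(pts)):
        rows = np.flatnonzero(cell == c)
        if len(rows) < min_cell_samples:
            continue
        X = np.column_stack([np.ones(len(rows)), omega[rows + t0]])
        beta, *_ = np.linalg.lstsq(X, y_all[rows], rcond=None)
        pred[rows] = X @ beta
    ok = np.isfinite(pred)
    unassigned = float(1.0 - ok.mean())
    if ok.sum() < 10:
        return np.nan, unassigned
    y = y_all[ok]
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - pred[ok]) ** 2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    return max(r2, 0.0), unassigned


def paired_comparison(
    a: np.ndarray,
    b: np.ndarray,
    kind: str = "paired",
) -> dict:
    """Wilcoxon tests between per-unit metric columns.

    kind='paired': signed-rank between columns a and b.
    kind='one-sample': signed-rank of a against zero (b ignored).
    Returns medians, effect direction and the p-value; ties-only input
    yields p = NaN with a flag.
    """
    a = np.asarray(a, dtype=float)
    if kind == "one-sample":
        diff = a
    else:
        b = np.asarray(b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired columns must have equal length")
        diff = b - a
    if len(diff) < 6:
        raise ValueError("need at least 6 units")
    out = {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)) if kind == "paired" else 0.0,
        "median_diff": float(np.median(diff)),
        "direction": "b>a" if np.median(diff) > 0 else ("a>b" if np.median(diff) < 0 else "none"),
        "n": int(len(diff)),
    }
    if np.allclose(diff, 0):
        # all ties: no difference detectable; flagged rather than silently NaN
        out["p"] = 1.0
        out["ties_only"] = True
        return out
    try:
        stat, p = stats.wilcoxon(diff)
    except ValueError:
        out["p"] = np.nan
        out["ties_only"] = True
        return out
    out["p"] = float(p)
    out["statistic"] = float(stat)
    out["ties_only"] = False
    return out
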