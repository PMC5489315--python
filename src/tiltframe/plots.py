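"""Figure helpers; plots are regenerable from exported tables, never the data of record."""

from __future__ import annotations

import numpy as np

from .tilt import TiltRateMap, lambert_project


def plot_tilt_map(rate_map: TiltRateMap, pole=(0.0, 0.0, 1.0), ax=None):
    """Scatter a spherical tilt rate map in Lambert equal-area coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pts = rate_map.grid.points
    hemi = pts @ np.asarray(pole) >= -1e-9  # front hemisphere plus equator
    xy = lambert_project(pts[hemi], pole)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=rate_map.mean_rate[hemi], s=18, cmap="viridis")
    eq = plt.Circle((0, 0), np.sqrt(2.0), fill=False, ls="--", color="gray")
    ax.add_patch(eq)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(sc, ax=ax, label="rate (Hz)")
    return ax


def plot_gain_lag(curve, ax=None):
    """Gain vs lag with the shuffle band if available."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve.lags * 1000, curve.gains, color="k")
    if curve.shuffle_band is not None:
        mu, sd = curve.shuffle_band
        ax.axhspan(mu - 2 * sd, mu + 2 * sd, color="gray", alpha=0.3)
    ax.axvline(curve.optimal_lag * 1000, ls=":", color="r")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("gain (Hz per °/s)")
    return ax
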