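"""Instantaneous firing rate, ISI statistics and discharge-based unit typing."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "UnitActivity",
    "UnitClass",
    "instantaneous_rate",
    "isi_statistics",
    "immobility_epochs",
    "classify_unit",
    "make_unit_activity",
]

ENTROPY_CUTOFF_BITS = 6.3
RATE_CUTOFF_HZ = 12.0
IMMOBILITY_SPEED_FLOOR = 15.0  # °/s
IMMOBILITY_MIN_DURATION = 1.0  # s


@dataclasses.dataclass
class UnitActivity:
    spike_times: np.ndarray
    fr_instant: np.ndarray     # Hz, on the kinematic grid
    mean_rate: float           # Hz, spike count / span
    isi_cv: float
    isi_entropy: float         # bits


@dataclasses.dataclass
class UnitClass:
    label: str                 # putative_mossy_fiber | putative_golgi | putative_purkinje
    entropy: float
    mean_rate: float


def instantaneous_rate(spike_times: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Reciprocal of the enclosing inter-spike interval, sampled on a grid.

    Timestamps before the first or after the last spike read 0.
    """
    spikes = np.asarray(spike_times, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    out = np.zeros_like(t)
    if len(spikes) < 2:
        warnings.warn("fewer than 2 spikes: instantaneous rate is all zero")
        return out
    idx = np.searchsorted(spikes, t, side="right")
    inside = (idx > 0) & (idx < len(spikes))
    isi = np.diff(spikes)
    out[inside] = 1.0 / isi[idx[inside] - 1]
    return out


def smoothed_rate(spike_times: np.ndarray, timestamps: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-kernel alternative rate estimate (off by default in the pipeline)."""
    spikes = np.asarray(spike_times, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    out = np.zeros_like(t)
    norm = 1.0 / (np.sqrt(2 * np.pi) * sigma)
    for s in spikes:
        lo, hi = np.searchsorted(t, [s - 5 * sigma, s + 5 * sigma])
        out[lo:hi] += norm * np.exp(-0.5 * ((t[lo:hi] - s) / sigma) ** 2)
    return out


def immobility_epochs(
    t: np.ndarray,
    omega: np.ndarray,
    speed_floor: float = IMMOBILITY_SPEED_FLOOR,
    min_duration: float = IMMOBILITY_MIN_DURATION,
) -> list[tuple[float, float]]:
    """Intervals where angular speed stays below the floor for >= min_duration."""
    speed = np.linalg.norm(omega, axis=1)
    still = speed < speed_floor
    runs = []
    i = 0
    n = len(still)
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            if t[j - 1] - t[i] >= min_duration:
                runs.append((float(t[i]), float(t[j - 1])))
            i = j
        else:
            i += 1
    return runs


def _restrict_isis(spikes: np.ndarray, epochs) -> np.ndarray:
    isis = []
    for lo, hi in epochs:
        seg = spikes[(spikes >= lo) & (spikes <= hi)]
        if len(seg) >= 2:
            isis.append(np.diff(seg))
    return np.concatenate(isis) if isis else np.array([])


def isi_statistics(
    spike_times: np.ndarray,
    immobility: "list[tuple[float, float]] | None" = None,
    entropy_bin_width: float = 0.02,
    entropy_range: tuple[float, float] = (1e-3, 10.0),
) -> tuple[float, float]:
    """(CV, Shannon entropy in bits) of the inter-spike-interval distribution.

    The entropy uses a fixed log2-ISI histogram: bins of ``entropy_bin_width``
    log2 units spanning ``entropy_range`` seconds.  When immobility epochs
    are given the CV and entropy are restricted to ISIs inside them.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if immobility is not None:
        isis = _restrict_isis(spikes, immobility)
    else:
        isis = np.diff(spikes)
    if len(isis) == 0:
        warnings.warn("no ISIs available: statistics undefined")
        return np.nan, np.nan
    if len(isis) < 50:
        warnings.warn(f"only {len(isis)} ISIs: statistics may be unstable")
    cv = float(isis.std() / isis.mean())
    log_isis = np.log2(np.clip(isis, *entropy_range))
    lo, hi = np.log2(entropy_range[0]), np.log2(entropy_range[1])
    nbins = int(np.ceil((hi - lo) / entropy_bin_width))
    counts, _ = np.histogram(log_isis, bins=nbins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return cv, entropy


def classify_unit(mean_rate: float, entropy: float) -> UnitClass:
    """Threshold classification by ISI entropy then mean rate.

    Entropy below 6.3 bits -> putative mossy fiber; otherwise rate below
    12 Hz -> putative Golgi cell; otherwise putative Purkinje cell.  Exact
    threshold values do not trip the cutoff (>= passes).
    """
    if not (np.isfinite(mean_rate) and np.isfinite(entropy)):
        raise ValueError("mean_rate and entropy must be finite")
    if entropy < ENTROPY_CUTOFF_BITS:
        label = "putative_mossy_fiber"
    elif mean_rate < RATE_CUTOFF_HZ:
        label = "putative_golgi"
    else:
        label = "putative_purkinje"
    return UnitClass(label=label, entropy=entropy, mean_rate=mean_rate)


def make_unit_activity(
    spike_times: np.ndarray,
    timestamps: np.ndarray,
    omega: "np.ndarray | None" = None,
) -> UnitActivity:
    """Bundle the derived discharge descriptors of one unit."""
    spikes = np.asarray(spike_times, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    fr = instantaneous_rate(spikes, t)
    span = t[-1] - t[0] if len(t) > 1 else np.nan
    mean_rate = float(np.sum((spikes >= t[0]) & (spikes <= t[-1])) / span) if span else np.nan
    epochs = immobility_epochs(t, omega) if omega is not None else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv, entropy = isi_statistics(spikes, immobility=epochs)
        if immobility_is_empty(epochs) or not np.isfinite(cv):
            cv, entropy = isi_statistics(spikes)
    return UnitActivity(
        spike_times=spikes, fr_instant=fr, mean_rate=mean_rate,
        isi_cv=cv, isi_entropy=entropy,
    )


def immobility_is_empty(epochs) -> bool:
    return epochs is not None and len(epochs) == 0
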