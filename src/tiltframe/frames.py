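"""Head-bound vs gravity-anchored reference-frame classification.

For every explored head-tilt region, rotational sensitivity vectors are
fitted twice — against head-frame and against earth-frame angular velocity.
If a unit encodes rotations in one frame, its vectors stay parallel across
tilts only in that frame.  Collinearity S (dot product of normalized
vectors) as a function of the angular distance φ between tilt positions
quantifies this; ΔS = S_external − S_internal averaged over φ ∈ [80°, 100°]
classifies the unit (external > 0.5, internal < −0.5).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .tilt import SphereGrid, cap_members

__all__ = [
    "SensitivityField",
    "CollinearityProfile",
    "FrameClassification",
    "local_sensitivity_field",
    "collinearity_profile",
    "classify_reference_frame",
    "delta_s",
]

DECISION_BAND = (80.0, 100.0)   # degrees
DECISION_CUTOFF = 0.5


@dataclasses.dataclass
class SensitivityField:
    grid: SphereGrid
    occupied: np.ndarray          # (m,) bool
    internal: np.ndarray          # (m, 3) head-frame components, NaN if unoccupied
    external: np.ndarray          # (m, 3) earth-frame components
    gain_internal: np.ndarray     # (m,)
    gain_external: np.ndarray
    elevation_internal: np.ndarray  # degrees above the (x, y) plane of its frame
    elevation_external: np.ndarray
    occupancy: np.ndarray         # (m,) sample counts
    significant: np.ndarray       # (m,) bool, per-cap shuffle test

    def n_occupied(self) -> int:
        return int(self.occupied.sum())


@dataclasses.dataclass
class CollinearityProfile:
    phi_bins: np.ndarray          # (nbin+1,) degree edges
    s_mean: np.ndarray            # (nbin,) mean pairwise collinearity, NaN if empty
    n_pairs: np.ndarray           # (nbin,)
    frame: str                    # 'internal' | 'external'


@dataclasses.dataclass
class FrameClassification:
    label: str                    # 'external' | 'internal' | 'unclassified'
    delta_s: float
    reason: str = ""


def _elevation_deg(vectors: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(vectors, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.degrees(np.arcsin(np.clip(vectors[..., 2] / norm, -1.0, 1.0)))


def _cap_fit(
    fr: np.ndarray, omega: np.ndarray, idx: np.ndarray, shift: int, n: int
) -> np.ndarray:
    valid = idx[(idx + shift >= 0) & (idx + shift < n)]
    X = np.column_stack([np.ones(len(valid)), omega[valid]])
    y = fr[valid + shift]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[1:4]


def local_sensitivity_field(
    fr: np.ndarray,
    omega_head: np.ndarray,
    omega_earth: np.ndarray,
    gravity_head: np.ndarray,
    grid: Optional[SphereGrid] = None,
    min_occupancy: int = 500,
    lag: float = 0.0,
    sample_rate: float = 250.0,
    n_shuffles: int = 20,
    shuffle_seed: int = 0,
) -> SensitivityField:
    """Tilt-binned internal/external sensitivity vectors at one lag.

    Per-cap significance: the internal gain must exceed mean + 2 SD of gains
    obtained with circularly shifted rate series (``n_shuffles=0`` disables
    the filter and marks every occupied cap significant).
    """
    if grid is None:
        grid = SphereGrid.default()
    fr = np.asarray(fr, dtype=float)
    n = len(fr)
    shift = int(round(lag * sample_rate))
    members = cap_members(np.asarray(gravity_head, dtype=float), grid.points, grid.cap_radius)
    m = len(grid.points)

    internal = np.full((m, 3), np.nan)
    external = np.full((m, 3), np.nan)
    occupancy = np.zeros(m, dtype=np.int64)
    occupied = np.zeros(m, dtype=bool)
    significant = np.zeros(m, dtype=bool)

    shuffled = []
    if n_shuffles > 0:
        rng = np.random.default_rng(shuffle_seed)
        min_off = max(n // 10, 1)
        offsets = rng.integers(min_off, n - min_off, size=n_shuffles)
        shuffled = [np.roll(fr, off) for off in offsets]

    for k, idx in enumerate(members):
        occupancy[k] = len(idx)
        if len(idx) < min_occupancy:
            continue
        occupied[k] = True
        internal[k] = _cap_fit(fr, omega_head, idx, shift, n)
        external[k] = _cap_fit(fr, omega_earth, idx, shift, n)
        if n_shuffles > 0:
            g_obs = np.linalg.norm(internal[k])
            g_null = np.array(
                [np.linalg.norm(_cap_fit(s, omega_head, idx, shift, n)) for s in shuffled]
            )
            significant[k] = g_obs > g_null.mean() + 2.0 * g_null.std()
        else:
            significant[k] = True

    return SensitivityField(
        grid=grid,
        occupied=occupied,
        internal=internal,
        external=external,
        gain_internal=np.linalg.norm(internal, axis=1),
        gain_external=np.linalg.norm(external, axis=1),
        elevation_internal=_elevation_deg(internal),
        elevation_external=_elevation_deg(external),
        occupancy=occupancy,
        significant=significant,
    )


def collinearity_profile(
    field: SensitivityField,
    frame: str,
    phi_bin_width: float = 10.0,
    require_significant: bool = True,
) -> CollinearityProfile:
    """Mean pairwise collinearity of normalized vectors, binned by tilt distance."""
    if frame not in ("internal", "external"):
        raise ValueError("frame must be 'internal' or 'external'")
    use = field.occupied & (field.significant if require_significant else True)
    pts_idx = np.flatnonzero(use)
    if len(pts_idx) < 3:
        raise ValueError("fewer than 3 occupied points: profile undefined")
    pts = field.grid.points[pts_idx]
    vecs = (field.internal if frame == "internal" else field.external)[pts_idx]
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)

    iu, ju = np.triu_indices(len(pts_idx), k=1)
    cosphi = np.clip(np.einsum("ij,ij->i", pts[iu], pts[ju]), -1.0, 1.0)
    phi = np.degrees(np.arccos(cosphi))
    s = np.einsum("ij,ij->i", vecs[iu], vecs[ju])

    edges = np.arange(0.0, 180.0 + phi_bin_width / 2, phi_bin_width)
    nbin = len(edges) - 1
    which = np.clip(np.digitize(phi, edges) - 1, 0, nbin - 1)
    n_pairs = np.bincount(which, minlength=nbin)
    sums = np.bincount(which, weights=s, minlength=nbin)
    s_mean = np.full(nbin, np.nan)
    nz = n_pairs > 0
    s_mean[nz] = sums[nz] / n_pairs[nz]
    return CollinearityProfile(phi_bins=edges, s_mean=s_mean, n_pairs=n_pairs, frame=frame)


def delta_s(
    profile_internal: CollinearityProfile,
    profile_external: CollinearityProfile,
    band: tuple[float, float] = DECISION_BAND,
) -> float:
    """Mean S_external − S_internal over the decision band of φ."""
    edges = profile_internal.phi_bins
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = (centers >= band[0]) & (centers <= band[1])
    s_int = profile_internal.s_mean[sel]
    s_ext = profile_external.s_mean[sel]
    ok = np.isfinite(s_int) & np.isfinite(s_ext)
    if not ok.any():
        return np.nan
    return float(np.mean(s_ext[ok] - s_int[ok]))


def classify_reference_frame(
    profile_internal: CollinearityProfile,
    profile_external: CollinearityProfile,
    cutoff: float = DECISION_CUTOFF,
    band: tuple[float, float] = DECISION_BAND,
) -> FrameClassification:
    ds = delta_s(profile_internal, profile_external, band)
    if not np.isfinite(ds):
        return FrameClassification(label="unclassified", delta_s=ds,
                                   reason="decision band empty")
    if ds > cutoff:
        return FrameClassification(label="external", delta_s=ds)
    if ds < -cutoff:
        return FrameClassification(label="internal", delta_s=ds)
    return FrameClassification(label="unclassified", delta_s=ds)
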