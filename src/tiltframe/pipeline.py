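"""Session loading and end-to-end orchestration of the analysis stages."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as tfio
from . import resampling, spiking, tilt, tuning
from .frames import classify_reference_frame, collinearity_profile, local_sensitivity_field
from .imu import KinematicSeries, estimate_orientation, kinematic_derivatives
from .models import REGRESSOR_SETS, global_linear_fit, local_linear_r2

logger = logging.getLogger("tiltframe")

__all__ = ["AnalysisConfig", "Session", "load_session", "run_analysis"]


@dataclasses.dataclass
class AnalysisConfig:
    correction_gain: float = 0.01
    target_median_neighbors: int = 200
    exclusion_window: float = 1.0
    min_neighbors: int = 10
    lag_grid_ms: tuple = (-500.0, 500.0, 20.0)     # start, stop, step
    query_stride: int = 4
    block_length: float = 30.0
    n_shuffles: int = 10
    grid_points: int = 642
    cap_radius: float = 20.0
    map_min_occupancy: int = 500
    hemifield_threshold: float = 0.25
    field_n_shuffles: int = 20
    gain_n_shuffles: int = 100
    min_spikes: int = 100
    expected_sample_rate: Optional[float] = None
    seed: int = 0

    @property
    def lag_grid(self) -> np.ndarray:
        lo, hi, step = self.lag_grid_ms
        return np.round(np.arange(lo, hi + step / 2, step) / 1000.0, 10)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lag_grid_ms"] = list(d["lag_grid_ms"])
        return d


@dataclasses.dataclass
class Session:
    kin: KinematicSeries
    units: dict                         # unit_id -> spike time array
    manifest: dict
    blocks: list = dataclasses.field(default_factory=list)
    truth: Optional[object] = None
    warnings: list = dataclasses.field(default_factory=list)


def load_session(manifest_path: "str | Path", config: Optional[AnalysisConfig] = None) -> Session:
    """Load and validate a session described by a YAML manifest."""
    config = config or AnalysisConfig()
    manifest_path = Path(manifest_path)
    manifest = tfio.read_manifest(manifest_path)
    base = manifest_path.parent
    problems: list[str] = []

    kin_path = base / manifest["kinematics"]
    if not kin_path.exists():
        raise FileNotFoundError(f"kinematics file missing: {kin_path}")
    kin = tfio.read_kinematics(kin_path)
    if config.expected_sample_rate and abs(kin.sample_rate - config.expected_sample_rate) > 1e-6:
        raise ValueError(
            f"kinematics at {kin.sample_rate} Hz but config demands "
            f"{config.expected_sample_rate} Hz (resampling is off by default)"
        )

    blocks = manifest.get("blocks", [])
    intervals = sorted((b["start"], b["stop"]) for b in blocks)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping blocks: ({s1},{e1}) and ({s2},{e2})")
    for s, e in intervals:
        if s < kin.t[0] - 1e-9 or e > kin.t[-1] + 1e-9:
            raise ValueError(f"block ({s},{e}) outside recording span")

    units = {}
    for entry in manifest.get("units", []):
        unit_id = entry["unit_id"]
        spike_path = base / entry["spike_file"]
        if not spike_path.exists():
            raise FileNotFoundError(f"spike file missing: {spike_path}")
        spikes = tfio.read_spike_times(spike_path)
        if len(spikes) < config.min_spikes:
            problems.append(f"unit {unit_id}: only {len(spikes)} spikes")
        units[unit_id] = spikes

    truth = None
    if manifest.get("ground_truth"):
        gt_path = base / manifest["ground_truth"]
        if gt_path.exists():
            truth = tfio.read_ground_truth(gt_path)

    for msg in problems:
        logger.warning(msg)
    return Session(kin=kin, units=units, manifest=manifest, blocks=blocks,
                   truth=truth, warnings=problems)


def analyze_unit(
    unit_id: str,
    spikes: np.ndarray,
    kin: KinematicSeries,
    orient,
    derived,
    config: AnalysisConfig,
) -> dict:
    """Full per-unit analysis; returns a JSON-serializable result dict."""
    t = kin.t
    fs = kin.sample_rate
    activity = spiking.make_unit_activity(spikes, t, omega=kin.omega)
    unit_class = spiking.classify_unit(activity.mean_rate, activity.isi_entropy)
    fr = activity.fr_instant

    result = {
        "unit_id": unit_id,
        "n_spikes": int(len(spikes)),
        "mean_rate": activity.mean_rate,
        "isi_cv": activity.isi_cv,
        "isi_entropy": activity.isi_entropy,
        "unit_class": unit_class.label,
        "config": config.to_dict(),
    }

    # model-free predictability per parameter set
    table = resampling.predictability_table(
        fr, t, kin, orient,
        lag_grid=config.lag_grid,
        target_median_neighbors=config.target_median_neighbors,
        exclusion_window=config.exclusion_window,
        min_neighbors=config.min_neighbors,
        query_stride=config.query_stride,
        seed=config.seed,
    )
    result["predictability"] = table
    result["selectivity"] = resampling.classify_inertial_selectivity(
        table["omega"]["r2"], table["ag"]["r2"]
    )

    # rotational tuning
    curve = tuning.gain_lag_curve(
        fr, kin.omega, fs, lag_grid=config.lag_grid,
        n_shuffles=config.gain_n_shuffles, seed=config.seed,
    )
    i_opt = int(np.argmin(np.abs(curve.lags - curve.optimal_lag)))
    result["tuning"] = {
        "gain": float(curve.gains[i_opt]),
        "optimal_lag": curve.optimal_lag,
        "significant": bool(curve.significant),
        "omega_opt": [float(x) for x in curve.vectors[i_opt]],
    }

    # tilt rate map
    try:
        rate_map = tilt.tilt_rate_map(
            fr, orient.gravity_head,
            tilt.SphereGrid.default(config.grid_points, config.cap_radius),
            min_occupancy=config.map_min_occupancy,
        )
        result["tilt_map_cv"] = rate_map.cv
    except ValueError as e:
        result["tilt_map_cv"] = None
        result.setdefault("errors", []).append(f"tilt map: {e}")

    # stability indices
    for axis in ("x", "y"):
        si = tilt.stability_index(
            fr, kin.omega, orient.gravity_head, axis, fs,
            threshold=config.hemifield_threshold,
        )
        result[f"sigma_{axis}"] = float(si.sigma) if np.isfinite(si.sigma) else None

    # reference frame
    try:
        field = local_sensitivity_field(
            fr, kin.omega, derived.omega_earth, orient.gravity_head,
            tilt.SphereGrid.default(config.grid_points, config.cap_radius),
            min_occupancy=config.map_min_occupancy,
            lag=curve.optimal_lag, sample_rate=fs,
            n_shuffles=config.field_n_shuffles, shuffle_seed=config.seed,
        )
        prof_i = collinearity_profile(field, "internal")
        prof_e = collinearity_profile(field, "external")
        cls = classify_reference_frame(prof_i, prof_e)
        result["reference_frame"] = {
            "label": cls.label,
            "delta_s": float(cls.delta_s) if np.isfinite(cls.delta_s) else None,
            "n_occupied": field.n_occupied(),
        }
    except ValueError as e:
        result["reference_frame"] = {"label": "unclassified", "delta_s": None}
        result.setdefault("errors", []).append(f"reference frame: {e}")
        field = None

    # model comparison
    regressors = {
        "omega": kin.omega, "omega_dot": derived.omega_dot,
        "ag": orient.gravity_head, "ag_dot": derived.gravity_jerk,
    }
    best_global = 0.0
    globals_ = {}
    for set_ in REGRESSOR_SETS:
        res = global_linear_fit(fr, regressors, set_, curve.optimal_lag, fs)
        globals_["+".join(set_)] = res.r2
        best_global = max(best_global, res.r2)
    result["global_r2"] = globals_
    if field is not None and field.occupied.sum() > 0:
        r2_local, unassigned = local_linear_r2(
            fr, kin.omega, orient.gravity_head,
            field.grid.points, field.occupied, curve.optimal_lag, fs,
        )
        result["local_r2"] = float(r2_local) if np.isfinite(r2_local) else None
    else:
        result["local_r2"] = None
    return result


def run_analysis(session: Session, config: AnalysisConfig, out_dir: "str | Path") -> dict:
    """Run every stage for every unit; failures isolate the unit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kin = session.kin
    orient = estimate_orientation(kin, correction_gain=config.correction_gain)
    derived = kinematic_derivatives(kin, orient)

    results = {}
    failures = {}
    for unit_id, spikes in sorted(session.units.items()):
        t_start = time.time()
        if len(spikes) < 2:
            failures[unit_id] = "fewer than 2 spikes"
            logger.warning("unit %s skipped: fewer than 2 spikes", unit_id)
            continue
        try:
            results[unit_id] = analyze_unit(unit_id, spikes, kin, orient, derived, config)
            logger.info("unit %s analyzed in %.1f s", unit_id, time.time() - t_start)
        except Exception as e:  # stage failure isolates the unit
            failures[unit_id] = str(e)
            logger.exception("unit %s failed", unit_id)

    bundle = {
        "config": config.to_dict(),
        "units": results,
        "failures": failures,
    }
    with open(out_dir / "report.json", "w") as f:
        json.dump(bundle, f, indent=2, sort_keys=True, default=_json_default)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
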