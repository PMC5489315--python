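"""Synthetic head-kinematics sessions and spike trains from planted tuning models.

The generator produces head-frame angular velocity as a slow, temporally
correlated tilt drift (Ornstein–Uhlenbeck angular rates) plus fast
band-limited rotational bursts (multi-peaked spectrum, roll attenuated),
integrates it exactly into a ground-truth orientation, and synthesizes the
accelerometer channel as gravity reaction + lever-arm tangential and
centripetal accelerations + white noise.  Units spike through a
time-rescaled gamma renewal process so the interval irregularity (ISI CV)
is a single knob.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from . import quaternions as qt
from .imu import GRAVITY, EARTH_UP, KinematicSeries

__all__ = [
    "SimulationConfig",
    "GateSpec",
    "TuningSpec",
    "GroundTruth",
    "simulate_head_kinematics",
    "simulate_unit",
    "planted_rate",
    "build_session_fixture",
]


@dataclasses.dataclass
class SimulationConfig:
    duration: float = 600.0           # s
    sample_rate: float = 250.0        # Hz
    tilt_correlation_time: float = 2.0  # s, OU time constant of the slow drift
    tilt_rate_scale: float = 12.0     # °/s stationary SD of the slow drift rates
    rotation_band_edges: Sequence[float] = (1.0, 4.0, 10.0, 20.0)
    rotation_scale: float = 55.0      # °/s, per-axis SD of the fast component
    band_weights: Sequence[float] = (1.0, 0.8, 0.5)
    roll_attenuation: float = 0.4     # multiplies the fast roll (x) component
    lever_arm: Sequence[float] = (-0.02, 0.0, -0.02)  # m, pivot -> sensor
    accel_noise_sd: float = 0.01      # g
    gyro_noise_sd: float = 0.5        # °/s
    seed: int = 0

    def validate(self) -> None:
        scalars = [
            self.duration, self.sample_rate, self.tilt_correlation_time,
            self.tilt_rate_scale, self.rotation_scale, self.roll_attenuation,
            self.accel_noise_sd, self.gyro_noise_sd,
        ]
        if not all(np.isfinite(scalars)):
            raise ValueError("non-finite simulation config value")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if not 0 < self.roll_attenuation <= 1:
            raise ValueError("roll_attenuation must lie in (0, 1]")
        if not np.all(np.isfinite(self.lever_arm)):
            raise ValueError("lever_arm must be finite")
        if len(self.rotation_band_edges) < 2:
            raise ValueError("need at least one rotation band")


@dataclasses.dataclass
class GateSpec:
    """Gate on one head-frame gravity component for gated_mixed units.

    mode 'on_off' multiplies the rotational term by 1 where the component
    exceeds the threshold and by 0 elsewhere; 'sign_flip' multiplies by ±1
    according to the side of the threshold.
    """

    component: str = "x"              # 'x' | 'y' | 'z'
    mode: str = "on_off"              # 'on_off' | 'sign_flip'
    threshold: float = 0.0            # g

    def apply(self, gravity_head: np.ndarray) -> np.ndarray:
        idx = {"x": 0, "y": 1, "z": 2}[self.component]
        above = gravity_head[:, idx] > self.threshold
        if self.mode == "on_off":
            return above.astype(float)
        if self.mode == "sign_flip":
            return np.where(above, 1.0, -1.0)
        raise ValueError(f"unknown gate mode {self.mode!r}")


@dataclasses.dataclass
class TuningSpec:
    kind: str                          # rotation_head_frame | rotation_earth_frame | tilt | gated_mixed | untuned
    baseline_rate: float = 20.0        # Hz
    gain: float = 0.0                  # Hz/(°/s) for rotation kinds, Hz for tilt
    preferred_axis: Sequence[float] = (0.0, 0.0, 1.0)
    preferred_tilt: Sequence[float] = (0.0, 0.0, 1.0)
    tilt_concentration: float = 4.0    # von Mises-Fisher kappa
    tilt_gain: float = 0.0             # Hz, additive tilt bump for gated_mixed
    response_lag: float = 0.0          # s; positive = firing follows movement
    isi_cv: float = 0.95
    gate: Optional[GateSpec] = None

    KINDS = ("rotation_head_frame", "rotation_earth_frame", "tilt", "gated_mixed", "untuned")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.isi_cv <= 0:
            raise ValueError("isi_cv must be positive")
        for name in ("preferred_axis", "preferred_tilt"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be unit norm")


@dataclasses.dataclass
class GroundTruth:
    orientation: np.ndarray            # (n, 4) true head->earth quaternions
    gravity_head: np.ndarray           # (n, 3) true a^G, g
    omega_earth: np.ndarray            # (n, 3) true earth-frame omega, °/s
    specs: dict = dataclasses.field(default_factory=dict)          # unit_id -> TuningSpec
    noiseless_rates: dict = dataclasses.field(default_factory=dict)  # unit_id -> (n,) Hz


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    if lo <= 0:
        sos = signal.butter(4, hi / nyq, btype="low", output="sos")
    else:
        sos = signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _ou_rates(
    rng: np.random.Generator, n: int, dt: float, tau: float, sd: float
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck process, (n, 3), °/s."""
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    u = np.empty((n, 3))
    u[0] = rng.standard_normal(3) * sd
    u[1:] = rng.standard_normal((n - 1, 3)) * b
    # x[k] = a*x[k-1] + u[k] is an IIR filter on the innovation sequence
    return signal.lfilter([1.0], [1.0, -a], u, axis=0)


def simulate_head_kinematics(config: SimulationConfig) -> tuple[KinematicSeries, GroundTruth]:
    """Generate one session of head kinematics with exact ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    dt = 1.0 / fs
    n = int(round(config.duration * fs))
    t = np.arange(n) * dt

    # slow tilt drift: OU angular rates, correlated over seconds
    omega = _ou_rates(rng, n, dt, config.tilt_correlation_time, config.tilt_rate_scale)

    # fast rotational bursts: band-limited noise per axis, multi-peaked spectrum
    edges = list(config.rotation_band_edges)
    weights = list(config.band_weights)
    if len(weights) != len(edges) - 1:
        raise ValueError("band_weights must have one entry per band")
    wnorm = np.sqrt(np.sum(np.square(weights)))
    for axis in range(3):
        fast = np.zeros(n)
        for (lo, hi), wgt in zip(zip(edges[:-1], edges[1:]), weights):
            fast += wgt * _bandlimited_noise(rng, n, fs, lo, hi)
        fast *= config.rotation_scale / wnorm
        if axis == 0:
            fast *= config.roll_attenuation
        omega[:, axis] += fast

    # exact orientation from piecewise-constant integration of omega
    q_true = qt.integrate_body_rates(np.deg2rad(omega), dt, np.array([1.0, 0, 0, 0]))
    gravity_head = qt.qrotate(qt.qconj(q_true), np.broadcast_to(EARTH_UP, (n, 3)))
    gravity_head /= np.linalg.norm(gravity_head, axis=1, keepdims=True)
    omega_earth = np.einsum("nij,nj->ni", qt.rotmats(q_true), omega)

    # accelerometer: gravity reaction + lever-arm terms + white noise
    r = np.asarray(config.lever_arm, dtype=float)
    w = np.deg2rad(omega)
    wdot = np.gradient(w, dt, axis=0)
    acc = gravity_head + (np.cross(wdot, r) + np.cross(w, np.cross(w, np.broadcast_to(r, w.shape)))) / GRAVITY
    acc = acc + rng.standard_normal((n, 3)) * config.accel_noise_sd

    omega_meas = omega + rng.standard_normal((n, 3)) * config.gyro_noise_sd

    kin = KinematicSeries(t=t, omega=omega_meas, acc=acc, sample_rate=fs)
    truth = GroundTruth(orientation=q_true, gravity_head=gravity_head, omega_earth=omega_earth)
    return kin, truth


def planted_rate(kin: KinematicSeries, truth: GroundTruth, spec: TuningSpec) -> np.ndarray:
    """Noiseless instantaneous rate λ(t) of a planted unit, rectified at 0.

    The rotational drive is evaluated at ``t - response_lag`` so that firing
    at time t reflects movement ``response_lag`` seconds earlier.
    """
    spec.validate()
    n = kin.n
    shift = int(round(spec.response_lag * kin.sample_rate))
    if shift >= n:
        raise ValueError("kinematics shorter than response lag")

    def lagged(series: np.ndarray) -> np.ndarray:
        if shift == 0:
            return series
        out = np.empty_like(series)
        if shift > 0:
            out[shift:] = series[:-shift]
            out[:shift] = series[0]
        else:
            out[:shift] = series[-shift:]
            out[shift:] = series[-1]
        return out

    axis = np.asarray(spec.preferred_axis, dtype=float)
    tilt_dir = np.asarray(spec.preferred_tilt, dtype=float)
    g_head = truth.gravity_head

    rate = np.full(n, float(spec.baseline_rate))
    if spec.kind == "rotation_head_frame":
        rate = rate + spec.gain * lagged(kin.omega @ axis)
    elif spec.kind == "rotation_earth_frame":
        rate = rate + spec.gain * lagged(truth.omega_earth @ axis)
    elif spec.kind == "tilt":
        kappa = spec.tilt_concentration
        rate = rate + spec.gain * np.exp(kappa * (g_head @ tilt_dir - 1.0))
    elif spec.kind == "gated_mixed":
        gate = spec.gate if spec.gate is not None else GateSpec()
        rate = rate + spec.gain * lagged(gate.apply(g_head) * (kin.omega @ axis))
        if spec.tilt_gain != 0.0:
            kappa = spec.tilt_concentration
            rate = rate + spec.tilt_gain * np.exp(kappa * (g_head @ tilt_dir - 1.0))
    elif spec.kind != "untuned":
        raise ValueError(f"unknown tuning kind {spec.kind!r}")
    return np.maximum(rate, 0.0)


def spikes_from_rate(
    rate: np.ndarray, t: np.ndarray, isi_cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times from a rate series via time-rescaled gamma renewal.

    Shape 1/CV²; intervals in rescaled (unit-rate) time are gamma with mean
    1, mapped back through the inverse of Λ(t) = ∫λ.  CV=1 is Poisson.
    """
    rate = np.maximum(np.asarray(rate, dtype=float), 0.0)
    if rate.max() <= 0:
        return np.array([])
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])  # Λ at bin edges
    edges = np.concatenate([t, [t[-1] + dt]])
    total = cum[-1]
    shape = 1.0 / (isi_cv * isi_cv)
    # expected interval count plus slack
    n_draw = int(total + 10 * np.sqrt(total) + 10)
    rescaled = np.cumsum(rng.gamma(shape, 1.0 / shape, size=n_draw))
    while rescaled[-1] < total:
        extra = np.cumsum(rng.gamma(shape, 1.0 / shape, size=n_draw)) + rescaled[-1]
        rescaled = np.concatenate([rescaled, extra])
    rescaled = rescaled[rescaled < total]
    return np.interp(rescaled, cum, edges)


def simulate_unit(
    kin: KinematicSeries,
    truth: GroundTruth,
    spec: TuningSpec,
    seed: int = 0,
) -> np.ndarray:
    """Spike-time array for one planted unit."""
    rate = planted_rate(kin, truth, spec)
    rng = np.random.default_rng(seed)
    return spikes_from_rate(rate, kin.t, spec.isi_cv, rng)


def build_session_fixture(
    config: SimulationConfig,
    specs: dict,
    out_dir: "str | Path",
    unit_seed_offset: int = 1000,
) -> Path:
    """Write a full session (kinematics, spikes, ground truth, manifest) to disk.

    Returns the manifest path.  Everything is deterministic in config.seed.
    """
    from . import io as tfio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kin, truth = simulate_head_kinematics(config)

    kin_path = out_dir / "kinematics.tsv"
    tfio.write_kinematics_tsv(kin_path, kin)

    unit_entries = []
    for i, (unit_id, spec) in enumerate(sorted(specs.items())):
        spikes = simulate_unit(kin, truth, spec, seed=config.seed + unit_seed_offset + i)
        truth.specs[unit_id] = spec
        truth.noiseless_rates[unit_id] = planted_rate(kin, truth, spec)
        spike_path = out_dir / f"{unit_id}.spikes.txt"
        tfio.write_spike_times(spike_path, spikes)
        unit_entries.append(
            {"unit_id": unit_id, "spike_file": spike_path.name, "kind": spec.kind,
             "n_spikes": int(len(spikes))}
        )

    truth_path = out_dir / "ground_truth.h5"
    tfio.write_ground_truth(truth_path, truth)

    manifest = {
        "kinematics": kin_path.name,
        "sample_rate": config.sample_rate,
        "duration": config.duration,
        "seed": config.seed,
        "ground_truth": truth_path.name,
        "units": unit_entries,
    }
    manifest_path = out_dir / "session.yaml"
    tfio.write_manifest(manifest_path, manifest)
    return manifest_path
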