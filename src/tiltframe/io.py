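"""Readers and writers for session artifacts.

Kinematics travel as TSV (columns ``t omega_x omega_y omega_z acc_x acc_y
acc_z``; s, °/s, g) or as an HDF5 group of named float64 arrays; spike
trains as one float per line; ground truth as HDF5 (quaternions scalar
first); manifests as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imu import KinematicSeries, OrientationSeries

KIN_COLUMNS = ["t", "omega_x", "omega_y", "omega_z", "acc_x", "acc_y", "acc_z"]


def write_kinematics_tsv(path: "str | Path", kin: KinematicSeries) -> None:
    arr = np.column_stack([kin.t, kin.omega, kin.acc])
    df = pd.DataFrame(arr, columns=KIN_COLUMNS)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_kinematics_tsv(path: "str | Path", sample_rate: "float | None" = None) -> KinematicSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in KIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinematics file {path} missing columns {missing}")
    t = df["t"].to_numpy()
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
        sample_rate = round(sample_rate, 6)
    return KinematicSeries(
        t=t,
        omega=df[["omega_x", "omega_y", "omega_z"]].to_numpy(),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        sample_rate=sample_rate,
    )


def write_kinematics_h5(path: "str | Path", kin: KinematicSeries) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=kin.t)
        f.create_dataset("omega", data=kin.omega)
        f.create_dataset("acc", data=kin.acc)
        f.attrs["sample_rate"] = kin.sample_rate


def read_kinematics_h5(path: "str | Path") -> KinematicSeries:
    import h5py

    with h5py.File(path, "r") as f:
        return KinematicSeries(
            t=f["t"][:], omega=f["omega"][:], acc=f["acc"][:],
            sample_rate=float(f.attrs["sample_rate"]),
        )


def read_kinematics(path: "str | Path") -> KinematicSeries:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return read_kinematics_h5(path)
    return read_kinematics_tsv(path)


def write_spike_times(path: "str | Path", spikes: np.ndarray) -> None:
    np.savetxt(path, np.asarray(spikes, dtype=float), fmt="%.17g")


def read_spike_times(path: "str | Path") -> np.ndarray:
    arr = np.loadtxt(path, ndmin=1, dtype=float)
    return arr


def write_ground_truth(path: "str | Path", truth) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("orientation", data=truth.orientation)  # (n, 4) w,x,y,z
        f.create_dataset("gravity_head", data=truth.gravity_head)
        f.create_dataset("omega_earth", data=truth.omega_earth)
        grp = f.create_group("noiseless_rates")
        for unit_id, rate in truth.noiseless_rates.items():
            grp.create_dataset(str(unit_id), data=rate)
        spec_grp = f.create_group("specs")
        for unit_id, spec in truth.specs.items():
            g = spec_grp.create_group(str(unit_id))
            g.attrs["kind"] = spec.kind
            g.attrs["baseline_rate"] = spec.baseline_rate
            g.attrs["gain"] = spec.gain
            g.attrs["response_lag"] = spec.response_lag
            g.attrs["isi_cv"] = spec.isi_cv
            g.create_dataset("preferred_axis", data=np.asarray(spec.preferred_axis))
            g.create_dataset("preferred_tilt", data=np.asarray(spec.preferred_tilt))


def read_ground_truth(path: "str | Path"):
    import h5py

    from .synthetic import GroundTruth

    with h5py.File(path, "r") as f:
        truth = GroundTruth(
            orientation=f["orientation"][:],
            gravity_head=f["gravity_head"][:],
            omega_earth=f["omega_earth"][:],
        )
        if "noiseless_rates" in f:
            for key in f["noiseless_rates"]:
                truth.noiseless_rates[key] = f["noiseless_rates"][key][:]
    return truth


def write_orientation_h5(path: "str | Path", orient: OrientationSeries) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("q_es", data=orient.q_es)
        f.create_dataset("gravity_head", data=orient.gravity_head)
        f.create_dataset("nongrav_head", data=orient.nongrav_head)


def write_manifest(path: "str | Path", manifest: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)


def read_manifest(path: "str | Path") -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
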