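"""File formats and run manifests.

Everything is plain text: YAML for configuration, CSV for tabular data
(time courses, diameter samples, binned densities, MID tables) and JSON
for manifests and fit reports.  Writers and readers round-trip; every CLI
run directory carries a manifest recording the seed, a hash of the
configuration and the package version, and no timestamps, so identical
invocations produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import Dataset
from .labeling import MIDVector
from .network import CultureCondition, Trajectory
from .pbm import NumberDensity, SizeGrid

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_diameters_csv",
    "read_diameters_csv",
    "write_density_csv",
    "read_density_csv",
    "write_mids_csv",
    "read_mids_csv",
    "save_dataset",
    "load_dataset",
    "load_config",
    "save_config",
    "condition_to_dict",
    "condition_from_dict",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory_csv(traj: Trajectory, path: str) -> None:
    """One row per time point: time_h, VCD, then extracellular species."""
    df = pd.DataFrame({"time_h": traj.times, "VCD": traj.vcd})
    for k, s in enumerate(traj.ext_ids):
        df[s] = traj.extracellular[:, k]
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str) -> Trajectory:
    df = pd.read_csv(path)
    species = [c for c in df.columns if c not in ("time_h", "VCD")]
    return Trajectory(
        times=df["time_h"].to_numpy(dtype=float),
        vcd=df["VCD"].to_numpy(dtype=float),
        ext_ids=species,
        extracellular=df[species].to_numpy(dtype=float),
        int_ids=[],
        intracellular=np.zeros((len(df), 0)),
        reaction_ids=[],
        fluxes=np.zeros((len(df), 0)),
    )


# ---------------------------------------------------------------------------
# aggregate sizes and densities
# ---------------------------------------------------------------------------


def write_diameters_csv(samples: Sequence[float], path: str) -> None:
    pd.DataFrame({"diameter_um": np.asarray(samples, dtype=float)}).to_csv(
        path, index=False
    )


def read_diameters_csv(path: str) -> np.ndarray:
    return pd.read_csv(path)["diameter_um"].to_numpy(dtype=float)


def write_density_csv(density: NumberDensity, path: str) -> None:
    df = pd.DataFrame(
        {
            "bin_edge_low": density.grid.edges[:-1],
            "bin_edge_high": density.grid.edges[1:],
            "density": density.values,
        }
    )
    df.to_csv(path, index=False)


def read_density_csv(path: str, time: float = 0.0) -> NumberDensity:
    df = pd.read_csv(path)
    edges = np.concatenate(
        (df["bin_edge_low"].to_numpy(dtype=float), [df["bin_edge_high"].iloc[-1]])
    )
    return NumberDensity(SizeGrid(edges), df["density"].to_numpy(dtype=float), time)


# ---------------------------------------------------------------------------
# MIDs
# ---------------------------------------------------------------------------


def write_mids_csv(mids: Sequence[MIDVector], path: str) -> None:
    rows = []
    for m in mids:
        for shift, frac in enumerate(m.fractions):
            rows.append({"metabolite": m.metabolite, "mass_shift": shift,
                         "fraction": frac})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mids_csv(path: str) -> list:
    df = pd.read_csv(path)
    out = []
    for met, grp in df.groupby("metabolite", sort=False):
        grp = grp.sort_values("mass_shift")
        out.append(MIDVector(met, grp["fraction"].to_numpy(dtype=float)))
    return out


# ---------------------------------------------------------------------------
# datasets and conditions
# ---------------------------------------------------------------------------


def condition_to_dict(cond: CultureCondition) -> dict:
    out = {
        "initial_concentrations": {
            k: float(v) for k, v in cond.initial_concentrations.items()
        },
        "initial_vcd": float(cond.initial_vcd),
        "duration_h": float(cond.duration_h),
        "oxygen_level": float(cond.oxygen_level),
        "label": cond.label,
    }
    if cond.oxygen_schedule:
        out["oxygen_schedule"] = [[float(t), float(v)] for t, v in cond.oxygen_schedule]
    return out


def condition_from_dict(d: Mapping) -> CultureCondition:
    return CultureCondition(
        initial_concentrations=dict(d["initial_concentrations"]),
        initial_vcd=d["initial_vcd"],
        duration_h=d.get("duration_h", 48.0),
        oxygen_level=d.get("oxygen_level", 1.0),
        oxygen_schedule=[tuple(x) for x in d["oxygen_schedule"]]
        if d.get("oxygen_schedule")
        else None,
        label=d.get("label", ""),
    )


def save_dataset(dataset: Dataset, directory: str) -> None:
    """Write <label>.csv (long format) plus <label>.condition.yaml."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for r in range(dataset.n_replicates):
        for t_idx, t in enumerate(dataset.times):
            row = {"replicate": r, "time_h": t}
            for i, var in enumerate(dataset.variables):
                row[var] = dataset.values[r, t_idx, i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(
        os.path.join(directory, f"{dataset.label}.csv"), index=False
    )
    save_config(
        condition_to_dict(dataset.condition),
        os.path.join(directory, f"{dataset.label}.condition.yaml"),
    )


def load_dataset(directory: str, label: str) -> Dataset:
    df = pd.read_csv(os.path.join(directory, f"{label}.csv"))
    cond = condition_from_dict(
        load_config(os.path.join(directory, f"{label}.condition.yaml"))
    )
    variables = [c for c in df.columns if c not in ("replicate", "time_h")]
    times = np.array(sorted(df["time_h"].unique()), dtype=float)
    reps = sorted(df["replicate"].unique())
    values = np.empty((len(reps), len(times), len(variables)))
    for ri, r in enumerate(reps):
        sub = df[df["replicate"] == r].sort_values("time_h")
        values[ri] = sub[variables].to_numpy(dtype=float)
    return Dataset(label, cond, times, variables, values)


def bundle_labels(directory: str) -> list:
    return sorted(
        f[: -len(".condition.yaml")]
        for f in os.listdir(directory)
        if f.endswith(".condition.yaml")
    )


# ---------------------------------------------------------------------------
# config + manifest
# ---------------------------------------------------------------------------


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: Mapping, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def config_hash(config) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(directory: str, seed: int, config=None, extra=None) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "package": "biosos",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config) if config is not None else None,
    }
    if extra:
        manifest.update(extra)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
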