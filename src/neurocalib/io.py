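"""Reading and writing the package's tabular artifacts.

Trajectories, sample tables and densities travel as plain CSV (via
pandas); HDF5 mirrors exist for every artifact (via h5py); configs are
YAML.  The Harris-Wilson network can be loaded either from a triplet of
CSV files (origin sizes, initial destination sizes, cost matrix) or
from one HDF5 group.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .forward_models import HWNetwork, StateTrajectory
from .sir_abm import CompartmentDensities


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

def write_trajectory_csv(traj: StateTrajectory, path, columns=None) -> None:
    d = traj.states.shape[1]
    columns = list(columns) if columns is not None else [f"x{i}" for i in range(d)]
    df = pd.DataFrame(traj.states, columns=columns)
    df.insert(0, "t", traj.times)
    df.to_csv(path, index=False)


def read_trajectory_csv(path, model_tag: str = "") -> StateTrajectory:
    df = pd.read_csv(path)
    return StateTrajectory(df["t"].to_numpy(),
                           df.drop(columns="t").to_numpy(), model_tag)


def write_trajectory_hdf5(traj: StateTrajectory, path, group: str = "trajectory") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("times", data=traj.times)
        g.create_dataset("states", data=traj.states)
        g.attrs["model_tag"] = traj.model_tag


def read_trajectory_hdf5(path, group: str = "trajectory") -> StateTrajectory:
    with h5py.File(path, "r") as f:
        g = f[group]
        return StateTrajectory(g["times"][()], g["states"][()],
                               g.attrs.get("model_tag", ""))


def densities_to_trajectory(dens: CompartmentDensities) -> StateTrajectory:
    return StateTrajectory(dens.times, dens.states(), model_tag="sir-abm")


def write_densities_csv(dens: CompartmentDensities, path) -> None:
    dens.to_frame().to_csv(path, index=False)


def read_densities_csv(path) -> CompartmentDensities:
    df = pd.read_csv(path)
    return CompartmentDensities(df["t"].to_numpy(), df["S"].to_numpy(),
                                df["I"].to_numpy(), df["R"].to_numpy())


# ----------------------------------------------------------------------
# Harris-Wilson networks
# ----------------------------------------------------------------------

def write_network_csv(net: HWNetwork, directory) -> None:
    """Write the three tables ``origins.csv``, ``sizes.csv``, ``costs.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"origin_size": net.origin_sizes}).to_csv(
        directory / "origins.csv", index=False)
    pd.DataFrame({"initial_size": net.initial_sizes}).to_csv(
        directory / "sizes.csv", index=False)
    pd.DataFrame(net.cost_matrix).to_csv(directory / "costs.csv", index=False)


def read_network_csv(directory) -> HWNetwork:
    directory = Path(directory)
    return HWNetwork(
        pd.read_csv(directory / "origins.csv")["origin_size"].to_numpy(),
        pd.read_csv(directory / "costs.csv").to_numpy(),
        pd.read_csv(directory / "sizes.csv")["initial_size"].to_numpy(),
    )


def write_network_hdf5(net: HWNetwork, path, group: str = "network") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("origin_sizes", data=net.origin_sizes)
        g.create_dataset("cost_matrix", data=net.cost_matrix)
        g.create_dataset("initial_sizes", data=net.initial_sizes)


def read_network_hdf5(path, group: str = "network") -> HWNetwork:
    with h5py.File(path, "r") as f:
        g = f[group]
        return HWNetwork(g["origin_sizes"][()], g["cost_matrix"][()],
                         g["initial_sizes"][()])


# ----------------------------------------------------------------------
# samples, densities, configs
# ----------------------------------------------------------------------

def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_samples_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_marginal_csv(md, path) -> None:
    pd.DataFrame({"grid": md.grid, "density": md.density}).to_csv(path, index=False)


def save_config(obj, path) -> None:
    """Serialize a (possibly nested) dataclass to YAML."""
    def convert(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {k: convert(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, tuple):
            return [convert(v) for v in x]
        if isinstance(x, (list, dict)):
            return (
                {k: convert(v) for k, v in x.items()}
                if isinstance(x, dict) else [convert(v) for v in x]
            )
        return x

    with open(path, "w") as fh:
        yaml.safe_dump(convert(obj), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
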