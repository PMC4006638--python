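"""Trajectory serialisation (HDF5) and analysis reports (JSON/CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .grid import GridSpec
from .integrators import Trajectory


def save_trajectory(path, traj: Trajectory, component_names=None,
                    grid: GridSpec | None = None, config: dict | None = None
                    ) -> None:
    """Write a trajectory to HDF5: one dataset per state component, time
    axis first, provenance and units as attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        nt = traj.states.shape[0]
        if component_names and grid is not None:
            block = int(np.prod(grid.shape))
            for i, name in enumerate(component_names):
                data = traj.states[:, i * block:(i + 1) * block]
                f.create_dataset(
                    name, data=data.reshape((nt,) + grid.shape)
                )
            f.attrs["components"] = list(component_names)
            f.attrs["grid_npoints"] = list(grid.shape)
            f.attrs["grid_spacing"] = grid.spacing
            f.attrs["grid_ndim"] = grid.ndim
        else:
            f.create_dataset("states", data=traj.states)
        f.attrs["provenance"] = json.dumps(traj.provenance, default=str)
        if config is not None:
            f.attrs["config"] = json.dumps(config, default=str)


def load_trajectory(path) -> tuple[Trajectory, dict]:
    """Read a trajectory back; returns (trajectory, metadata).

    Metadata carries component names, the grid and the config echo when
    present.  The flat state ordering round-trips bitwise.
    """
    with h5py.File(path, "r") as f:
        times = f["times"][...]
        meta: dict = {"provenance": json.loads(f.attrs.get("provenance", "{}"))}
        if "config" in f.attrs:
            meta["config"] = json.loads(f.attrs["config"])
        if "components" in f.attrs:
            names = [str(n) for n in f.attrs["components"]]
            shape = tuple(int(n) for n in f.attrs["grid_npoints"])
            grid = GridSpec(int(f.attrs["grid_ndim"]), shape,
                            float(f.attrs["grid_spacing"]))
            nt = times.shape[0]
            block = int(np.prod(shape))
            states = np.empty((nt, len(names) * block))
            for i, name in enumerate(names):
                states[:, i * block:(i + 1) * block] = (
                    f[name][...].reshape(nt, block)
                )
            meta["components"] = names
            meta["grid"] = grid
        else:
            states = f["states"][...]
    traj = Trajectory(times=times, states=states,
                      provenance=meta["provenance"])
    return traj, meta


def write_dispersion_csv(path, curve) -> None:
    """CSV export of (q, alpha, omega) triples."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = np.column_stack([curve.q, curve.alpha, curve.omega])
    header = "q_rad_per_cm,alpha_per_s,omega_rad_per_s"
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def write_json(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
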