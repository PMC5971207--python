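"""Serialization helpers: YAML configs, HDF5 trajectory/count bundles, CSV export."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = [
    "load_yaml",
    "dump_yaml",
    "config_hash",
    "save_trajectories",
    "load_trajectories",
    "save_counts",
    "load_counts",
    "write_events_csv",
]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(obj: dict) -> str:
    """Stable short hash of a JSON-serializable config, for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_trajectories(path, V: np.ndarray, times: np.ndarray, dt: float,
                      seed: int, r: np.ndarray | None = None) -> None:
    """HDF5 layout: datasets /V (trials x T x N), /times, optional /r;
    attributes dt (ms) and seed."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("V", data=V, compression="gzip")
        fh.create_dataset("times", data=times)
        if r is not None:
            fh.create_dataset("r", data=r, compression="gzip")
        fh.attrs["dt"] = dt
        fh.attrs["seed"] = seed


def load_trajectories(path):
    with h5py.File(path, "r") as fh:
        V = fh["V"][...]
        times = fh["times"][...]
        r = fh["r"][...] if "r" in fh else None
        return V, times, r, dict(fh.attrs)


def save_counts(path, counts_by_condition: dict[str, np.ndarray],
                bin_ms: float, seed: int) -> None:
    """HDF5 bundle of (trials x bins x neurons) count arrays keyed by condition."""
    with h5py.File(path, "w") as fh:
        for label, arr in counts_by_condition.items():
            fh.create_dataset(label, data=arr, compression="gzip")
        fh.attrs["bin_ms"] = bin_ms
        fh.attrs["seed"] = seed


def load_counts(path):
    with h5py.File(path, "r") as fh:
        data = {k: fh[k][...] for k in fh}
        return data, dict(fh.attrs)


def write_events_csv(path, ids: np.ndarray, times: np.ndarray) -> None:
    """Two-column spike events (neuron_id, time_ms), one file per trial."""
    arr = np.column_stack([ids, times])
    np.savetxt(path, arr, fmt=["%d", "%.4f"], delimiter=",",
               header="neuron_id,time_ms", comments="")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
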