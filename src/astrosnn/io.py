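"""Checkpoint persistence (HDF5) and CSV exports."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .snn import WeightMatrix

__all__ = ["save_checkpoint", "load_checkpoint", "export_weights_csv"]


def save_checkpoint(path, w: WeightMatrix, theta: np.ndarray,
                    config: dict | None = None,
                    extra: dict | None = None) -> None:
    """Write weights, fault mask, theta and a config snapshot to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("w", data=w.w)
        fh.create_dataset("fault_mask", data=w.fault_mask)
        fh.create_dataset("theta", data=np.asarray(theta, dtype=float))
        fh.attrs["w_max"] = w.w_max
        fh.attrs["w_norm"] = w.w_norm
        fh.attrs["w_recurrent"] = w.w_recurrent
        if config is not None:
            fh.attrs["config_json"] = json.dumps(config, default=str)
        for key, value in (extra or {}).items():
            fh.create_dataset(f"extra/{key}", data=value)


def load_checkpoint(path):
    """Read a checkpoint back as ``(WeightMatrix, theta, config_dict)``."""
    with h5py.File(path, "r") as fh:
        w = WeightMatrix(
            w=fh["w"][...],
            fault_mask=fh["fault_mask"][...].astype(bool),
            w_max=float(fh.attrs["w_max"]),
            w_norm=float(fh.attrs["w_norm"]),
            w_recurrent=float(fh.attrs["w_recurrent"]),
        )
        theta = fh["theta"][...]
        config = (json.loads(fh.attrs["config_json"])
                  if "config_json" in fh.attrs else {})
    return w, theta, config


def export_weights_csv(path, w: WeightMatrix) -> None:
    """Plain CSV export of the weight matrix (rows: inputs, cols: neurons)."""
    header = ",".join(f"n{j}" for j in range(w.n_neurons))
    np.savetxt(path, w.w, delimiter=",", header=header, comments="")
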