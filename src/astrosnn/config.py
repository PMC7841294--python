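"""YAML config loading and packaged default scenarios.

Every numeric field of the parameter dataclasses can be overridden from a
plain key/value YAML file; nested sections mirror the dataclass structure.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass, replace

import numpy as np
import yaml

from .harness import ExperimentConfig
from .tripartite import ToyNetworkConfig

__all__ = [
    "load_yaml",
    "update_dataclass",
    "fig2_toy_config",
    "fig8_toy_config",
    "desk_experiment_config",
]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def update_dataclass(obj, overrides: dict):
    """Return a copy of dataclass *obj* updated (recursively) from a dict."""
    changes = {}
    names = {f.name for f in fields(obj)}
    for key, value in overrides.items():
        if key not in names:
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            changes[key] = update_dataclass(current, value)
        else:
            changes[key] = value
    return replace(obj, **changes)


def fig2_toy_config(seed: int = 0) -> ToyNetworkConfig:
    """The canonical two-neuron self-repair scenario: 400 s simulation,
    faults in 70% of N2's synapses at 200 s, all PR0 = 0.5."""
    return ToyNetworkConfig(
        n_post=2, n_pre_per_post=10, pre_rate=10.0, duration=400.0,
        fault_schedule=[(200.0, 1, 0.7)], pr0=0.5, seed=seed)


def fig8_toy_config(seed: int = 0) -> ToyNetworkConfig:
    """Heterogeneous-PR0 scenario: 9 of N2's synapses start at 0.5 and one at
    0.1; at 200 s the 8 high-PR0 synapses (other than the probe) die."""
    pr0 = np.full((2, 10), 0.5)
    pr0[1, 9] = 0.1  # the weak probe synapse on N2
    return ToyNetworkConfig(
        n_post=2, n_pre_per_post=10, pre_rate=10.0, duration=400.0,
        fault_schedule=[(200.0, 1, list(range(8)))],  # synapse 8 survives at 0.5
        pr0=pr0, seed=seed)


def desk_experiment_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale synthetic experiment defaults (16x16, 10 classes,
    50 neurons)."""
    return ExperimentConfig(seed=seed)
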