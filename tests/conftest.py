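"""Shared fixtures.

The desk-scale experiment fixture runs the full train/fault/normalize/repair
protocol once per session (5 seeds, fault levels 0.5/0.8 plus a fault-only
0.9 level) and is shared by the pipeline-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from astrosnn.harness import ExperimentConfig, run_experiment

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def desk_experiment():
    """Full experiment record on the default synthetic task (5 seeds)."""
    return run_experiment(ExperimentConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
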