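"""Shared fixtures.

The expensive end-to-end fixture-profile experiment (synthetic dataset,
two-stage training, held-out scoring) runs once per session and is shared by
every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from fruitscan import pipeline
from fruitscan.aunet import ArchConfig
from fruitscan.gdm import GSAMConfig
from fruitscan.model import DefectInspector


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_arch() -> ArchConfig:
    """Smallest architecture that still has the full 4-level geometry."""
    return ArchConfig(input_side=16, base_channels=2, init_std=0.1)


@pytest.fixture()
def tiny_model(tiny_arch) -> DefectInspector:
    return DefectInspector(tiny_arch, GSAMConfig(), rng=0)


@pytest.fixture(scope="session")
def fixture_run() -> dict:
    """The full desk-scale experiment: 64 training / 32 test images at
    128x128 with 8 base channels, trained with the two-stage protocol."""
    return pipeline.run_fixture_experiment(seed=0)
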