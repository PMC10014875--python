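"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from explore.labeling import ClassScheme
from explore.network import NetworkSpec
from explore.synthetic import ArenaConfig, generate_experiment


@pytest.fixture(scope="session")
def scheme3() -> ClassScheme:
    return ClassScheme.for_objects(2)


@pytest.fixture(scope="session")
def tiny_spec() -> NetworkSpec:
    """A shrunken network for fast training-mechanics tests."""
    return NetworkSpec(
        input_size=14, conv_filters=(4, 8), dense_units=(16,), dropout_rate=0.0
    )


@pytest.fixture(scope="session")
def short_experiment():
    """One 30 s synthetic video at 10 fps, two objects, normal contrast."""
    config = ArenaConfig(duration_s=30.0, fps=10.0)
    return generate_experiment(config, 1, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
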