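import dataclasses

import numpy as np
import pytest

from hfosnn.config import PipelineConfig
from hfosnn.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def base_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def syn_config() -> SyntheticConfig:
    """Small, fast synthetic recording config (no events)."""
    return SyntheticConfig(n_channels=1, duration=12.0, fs=2000.0, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def event_recording(base_config):
    """One 30 s channel containing every event kind, with ground truth."""
    from hfosnn.synthetic import generate_recording

    syn = dataclasses.replace(
        base_config.synthetic,
        n_channels=1,
        duration=30.0,
        seed=3,
        event_counts={"hfo": 3, "ied": 2, "ied_hfo": 2, "step_artifact": 2, "long_artifact": 1},
    )
    return generate_recording(syn)
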