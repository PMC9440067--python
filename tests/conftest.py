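import numpy as np
import pandas as pd
import pytest

from spongiome.config import SimulationConfig
from spongiome import synthetic
from spongiome.data import FeatureTable, SampleMetadata


@pytest.fixture(scope="session")
def default_dataset():
    """Small default synthetic bundle shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Noise-free limit: exclusive prevalence 1, huge dispersion, no decay."""
    cfg = SimulationConfig(
        seed=21, exclusive_prevalence=1.0, dispersion=1e9,
        decay_rate=0.0, env_effect_size=0.0,
    )
    return synthetic.generate_dataset(cfg)


@pytest.fixture
def toy_table():
    counts = np.array([
        [5, 0, 2, 1],
        [0, 3, 0, 0],
        [1, 1, 1, 1],
    ])
    return FeatureTable(counts, ["f1", "f2", "f3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_metadata():
    frame = pd.DataFrame(
        {
            "sample_type": ["sponge", "sponge", "seawater", "sediment"],
            "sponge_type": ["HMA", "LMA_demo", None, None],
            "host_species": ["spA", "spB", None, None],
            "location_id": ["L1", "L2", "L1", "L2"],
            "lat": [60.0, 61.0, 60.0, 61.0],
            "lon": [-20.0, -21.0, -20.0, -21.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample-id"),
    )
    return SampleMetadata(frame)
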