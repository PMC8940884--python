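import numpy as np
import pytest

from rhizoassembly import CountTable, GeneratorConfig, generate_study
from rhizoassembly.io_formats import SampleMetadata
import pandas as pd


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study configuration for fast end-to-end tests."""
    return GeneratorConfig(
        n_taxa=300,
        n_soil=2,
        n_reps=5,
        depth_soil=1500,
        depth_root=800,
        richness_reduction=0.15,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One seeded study under the default (full-size) configuration."""
    return generate_study(GeneratorConfig(rng_seed=5))


@pytest.fixture
def tiny_table():
    return CountTable(
        ["S1", "S2", "S3"],
        ["t1", "t2", "t3", "t4"],
        np.array([[5, 0, 2, 1], [10, 10, 0, 0], [1, 2, 3, 0]]),
    )


@pytest.fixture
def tiny_metadata():
    df = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "plant": ["wheat", "wheat", "faba_bean"],
            "sample_type": ["soil", "rhizosphere", "rhizoplane"],
            "replicate": [1, 1, 1],
        }
    ).set_index("sample_id")
    return SampleMetadata(df)
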