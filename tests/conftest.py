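import numpy as np
import pytest
from hypothesis import settings

from netseq_fidelity.simulate import SimConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_911)


@pytest.fixture(scope="session")
def small_config():
    """Small but realistic run: 20 kb genome, 8 genes, 8000 reads."""
    return SimConfig(
        genome_length=20_000,
        n_genes=8,
        n_ecs=8_000,
        misinc_fraction=0.05,
        seed=424_242,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No biological or experimental errors: reads are exact substrings."""
    return SimConfig(
        genome_length=20_000,
        n_genes=8,
        n_ecs=3_000,
        misinc_fraction=0.0,
        rt_error_rate=0.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        seed=99,
    )


@pytest.fixture(scope="session")
def clean_bundle(clean_config):
    return simulate(clean_config)
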