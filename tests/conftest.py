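import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from heterophylly.pipeline import Bundle, run_all
from heterophylly.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-scale synthetic study used by most integration tests."""
    return SimulationConfig(
        seed=11,
        n_rna_per_class={"mRNA": 400, "miRNA": 40, "lncRNA": 60, "circRNA": 30},
        n_sponge_triads=6,
        n_extra_silencing=6,
        term_size_range=(5, 50),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_result(small_dataset):
    return run_all(Bundle.from_synthetic(small_dataset))
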