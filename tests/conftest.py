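import pytest

from saltgrip.simulate import (
    SimConfig,
    simulate_fragment_library,
    simulate_truth,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One full synthetic truth shared across the suite."""
    catalog, truth, genome = simulate_truth(default_config)
    return catalog, truth, genome


@pytest.fixture(scope="session")
def salt_libraries(default_config, default_dataset):
    catalog, truth, _ = default_dataset
    conds = default_config.salt_labels + ("xchip",)
    return {
        c: simulate_fragment_library(truth, catalog, c, default_config)
        for c in conds
    }
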