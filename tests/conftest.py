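import pytest

from clonefate import GeneratorConfig, generate_library, simulate_coculture


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale experiment: 150 clones, default noise and design."""
    return GeneratorConfig(n_clones=150, depth_per_barcode=60.0, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    library, truth = generate_library(small_config)
    return library, truth


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    _, truth = small_truth
    return simulate_coculture(truth, small_config)
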