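import numpy as np
import pytest

from ndamda.synthetic import SyntheticConfig, generate_bundle, toy_fixture


@pytest.fixture(scope="session")
def toy():
    """The fixed 8 miRNA x 6 disease instance with hand-checkable values."""
    return toy_fixture()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down planted-cluster configuration for fast end-to-end tests."""
    return SyntheticConfig(
        n_mirnas=30,
        n_diseases=15,
        n_clusters=3,
        within_cluster_assoc_prob=0.4,
        background_assoc_prob=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
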