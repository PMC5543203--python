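import numpy as np
import pytest

from ki67assay.synthetic import HistologyConfig, generate_cellmap


@pytest.fixture(scope="session")
def clean_config():
    return HistologyConfig(theta=0.2)


@pytest.fixture(scope="session")
def clean_map(clean_config):
    return generate_cellmap(clean_config, seed=11)


@pytest.fixture(scope="session")
def clean_maps(clean_config):
    return [generate_cellmap(clean_config, seed=s) for s in (11, 12, 13)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
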