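import numpy as np
import pytest

from clmsi.chem import default_species_space
from clmsi.imaging import RegionMask
from clmsi.synthetic import GeneratorConfig, generate_imaging_dataset


@pytest.fixture(scope="session")
def species_space():
    return default_species_space()


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(rows=4, cols=4, seed=7)


@pytest.fixture(scope="session")
def nl_dataset(small_config):
    """One small normal-grey-matter section plus its ground truth."""
    dataset, truth = generate_imaging_dataset(small_config)
    return dataset, truth


@pytest.fixture(scope="session")
def nl_mask(small_config):
    return RegionMask(small_config.layout_array())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
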