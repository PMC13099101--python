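import numpy as np
import pytest

from ecopipe.io import default_biophysical, default_carbon_pools
from ecopipe.landscape import GeneratorConfig, generate_landscape


@pytest.fixture(scope="session")
def small_grid():
    grid, _ = generate_landscape(GeneratorConfig(nrows=24, ncols=24), seed=7)
    return grid


@pytest.fixture(scope="session")
def pools():
    return default_carbon_pools()


@pytest.fixture(scope="session")
def bio():
    return default_biophysical()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
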