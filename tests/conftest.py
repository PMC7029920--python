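import numpy as np
import pytest

from morphonorm.io import FactorDesign
from morphonorm.synthesis import default_effects, make_base_shape, simulate_sample


@pytest.fixture(scope="session")
def small_template():
    """A reduced valve-pair template: 5 fixed + 26 curve + 40 surface points."""
    return make_base_shape(5, (10, 10, 6), 40)


@pytest.fixture(scope="session")
def small_sample(small_template):
    """A full-design synthetic sample on the reduced template (n = 139)."""
    effects = default_effects(small_template.config, seed=11,
                              pairing=small_template.pairing)
    sample, truth = simulate_sample(effects, FactorDesign(), base=small_template)
    return sample, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
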