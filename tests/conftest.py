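import numpy as np
import pytest

from tntlearn import make_additive, make_clinical_like


@pytest.fixture(scope="session")
def clinical_small():
    """Small clinical-style dataset shared across fast tests."""
    return make_clinical_like(n=300, d=10, informative=4, seed=101)


@pytest.fixture(scope="session")
def additive_small():
    return make_additive(
        n=400, coefficients=[2.0, -1.0, 0.0, 0.0], noise_sd=0.1, seed=102
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
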