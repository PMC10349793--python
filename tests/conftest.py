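import numpy as np
import pytest

from duodose import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return make_phantom(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230715)
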