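import numpy as np
import pytest

import spinemetrics as sm


@pytest.fixture(scope="session")
def phantom_160():
    """A mid-size healthy phantom shared by read-only tests."""
    return sm.generate_phantom(sm.PhantomSpec.scaled(160, seed=11))


@pytest.fixture(scope="session")
def phantom_96():
    """A small healthy phantom for cheap structural checks."""
    return sm.generate_phantom(sm.PhantomSpec.scaled(96, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_label(rng, shape=(10, 10), classes=(1, 2, 3, 4, 5, 6)):
    return rng.choice(np.asarray(classes), size=shape).astype(np.int16)
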