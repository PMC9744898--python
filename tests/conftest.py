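import numpy as np
import pytest

from eknn.dataset import make_separable_fixture, simulate_uniform

TABLE1_N4 = {
    1: (), 2: (1,), 3: (1, 2), 4: (1, 2, 3), 5: (1, 2, 3, 4), 6: (1, 2, 4),
    7: (1, 3), 8: (1, 3, 4), 9: (1, 4), 10: (2,), 11: (2, 3), 12: (2, 3, 4),
    13: (2, 4), 14: (3,), 15: (3, 4), 16: (4,),
}


@pytest.fixture(scope="session")
def uniform_10x6():
    return simulate_uniform(m=10, n=6, n_classes=2, seed=3)


@pytest.fixture(scope="session")
def separable_20x4():
    return make_separable_fixture(m=20, n=4, informative=2, gap=2.0, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
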