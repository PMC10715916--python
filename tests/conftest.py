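import numpy as np
import pytest

from opinionet import make_belief_grid


@pytest.fixture(scope="session")
def grid():
    return make_belief_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_distribution(rng, n_points=200, peaked=False):
    """A random normalised mass vector; optionally sharply peaked."""
    w = rng.random(n_points)
    if peaked:
        w = w ** 8
    return w / w.sum()
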