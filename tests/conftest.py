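import numpy as np
import pytest

import infomech as im

TRUTH = {"mu": 1.0e6, "eta": 1.0e7, "A": 1.5e4}


@pytest.fixture(scope="session")
def bounds():
    return im.default_bounds()


@pytest.fixture(scope="session")
def protocol():
    return im.DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def truth():
    return im.DEFAULT_TRUTH


@pytest.fixture(scope="session")
def noisy_obs(truth, protocol):
    """One seeded realization of the reference synthetic experiment."""
    return im.generate("H1", truth, protocol, seed=0)


@pytest.fixture(scope="session")
def posterior(noisy_obs):
    """Reference H1 posterior at the default 2^16 Monte-Carlo samples."""
    return im.reconstruct("H1", noisy_obs, seed=0)
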