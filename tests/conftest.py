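import warnings

import numpy as np
import pytest

from mrckit import msh_to_mrc, random_msh_fixture, triad_fixture


@pytest.fixture(scope="session")
def triad_small():
    """Packaged triad model at a reduced mode count (fast tests).

    The printed reorganization table carries a known Gram defect, so the
    loader warns; that warning is itself under test elsewhere.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return triad_fixture("triad_conf3", n_modes=24)


@pytest.fixture(scope="session")
def triad_full():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return triad_fixture("triad_conf3", n_modes=200)


@pytest.fixture(scope="session")
def random4():
    return random_msh_fixture(4, 32, seed=7)


@pytest.fixture(scope="session")
def random4_mrc(random4):
    return msh_to_mrc(random4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
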