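import numpy as np
import pytest

from sodepr.presets import W_BAND, ZFS_PRESETS
from sodepr.synthetic_data import build_toy_site, tensors_from_site


@pytest.fixture(scope="session")
def w_band():
    return W_BAND


@pytest.fixture(scope="session")
def zfs_presets():
    return ZFS_PRESETS


@pytest.fixture(scope="session")
def toy_site():
    return build_toy_site("MnSOD_like", seed=1)


@pytest.fixture(scope="session")
def toy_tensors(toy_site):
    return tensors_from_site(toy_site)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
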