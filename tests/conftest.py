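import numpy as np
import pytest

from spectromics.chromophores import load_default_library
from spectromics.grids import default_grid
from spectromics.lut import build_default_lut


@pytest.fixture(scope="session")
def lib():
    return load_default_library()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def lut():
    """Shared default reflectance table (built once per session)."""
    return build_default_lut()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
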