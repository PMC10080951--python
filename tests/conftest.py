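import numpy as np
import pytest

from perisum.mosaic import build_hex_mosaic
from perisum.pooling import RetinalContext, UniformContext


@pytest.fixture(scope="session")
def small_mosaic():
    """~500-cell mosaic, cheap enough for brute-force pooling oracles."""
    return build_hex_mosaic(density=64.0, extent=(3.0, 3.0))


@pytest.fixture(scope="session")
def context100():
    """Full-mosaic retinal context at 100 RGC/deg2, optics off."""
    return RetinalContext(rgc_density=100.0)


@pytest.fixture(scope="session")
def uniform_context():
    return UniformContext(rgc_density=121.4, convergence=7.6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
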