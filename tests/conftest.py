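import numpy as np
import pytest

from mtarray import Geometry, KineticConstants


@pytest.fixture(scope="session")
def kinetics() -> KineticConstants:
    return KineticConstants()


@pytest.fixture(scope="session")
def geometry() -> Geometry:
    return Geometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
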