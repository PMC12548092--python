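import numpy as np
import pytest

from akfray.constants import PhysicalConstants


@pytest.fixture
def consts850() -> PhysicalConstants:
    return PhysicalConstants(field_mhz=850.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
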