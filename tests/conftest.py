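import numpy as np
import pytest

from sipivot import get_guide


@pytest.fixture(scope="session")
def sirl():
    return get_guide("siRL")


@pytest.fixture(scope="session")
def sipcsk9():
    return get_guide("siPCSK9-A1")


@pytest.fixture(scope="session")
def mir124():
    return get_guide("miR-124")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
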