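import numpy as np
import pytest

from thermoscan.descriptor import fouru_descriptor


@pytest.fixture(scope="session")
def fouru():
    return fouru_descriptor()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
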