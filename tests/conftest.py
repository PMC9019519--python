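import numpy as np
import pytest

from sigseq import nominal_params


@pytest.fixture(scope="session")
def nominal():
    return nominal_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
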