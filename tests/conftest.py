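import numpy as np
import pytest

from tdcea import default_parameter_set


@pytest.fixture(scope="session")
def base_ps():
    return default_parameter_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170925)
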