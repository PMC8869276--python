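import numpy as np
import pytest

from thermofatigue.timeline import make_default_timeline


@pytest.fixture(scope="session")
def default_timeline():
    """Standard protocol: 5-min baseline, sets of 60/50/40 s with 3-min
    rests, 5-min recovery; total 1110 s."""
    return make_default_timeline([60.0, 50.0, 40.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20220217)
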