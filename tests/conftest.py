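import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fep_rsi.generative_model import make_default_model


@pytest.fixture
def default_model():
    """The standard 5-state unit: noise 0.2, sharp preference for obs 4."""
    return make_default_model(
        n_states=5, likelihood_noise=0.2, preferred_obs=4,
        preference_sharpness=4.0,
    )


@pytest.fixture
def noise_free_model():
    return make_default_model(
        n_states=5, likelihood_noise=0.0, preferred_obs=4,
        preference_sharpness=4.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
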