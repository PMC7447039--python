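import numpy as np
import pandas as pd
import pytest

from temporalchoice import cohort
from temporalchoice.discount import DiscountParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def choice_design():
    """Default full-cross design, shuffled, 162 trials over 2 runs."""
    return cohort.make_choice_design(rng=np.random.default_rng(1))


@pytest.fixture
def gen_params():
    return DiscountParams(model="generalized_hyperbolic", k=0.01, s=1.5, beta_temp=1.0)


@pytest.fixture
def toy_trials():
    """Five hand-picked trials used by the LOO oracle tests."""
    return pd.DataFrame({
        "reward_ll": [20, 15, 12, 18, 11],
        "delay": [180, 10, 40, 90, 5],
        "choice": ["SS", "LL", "SS", "LL", "LL"],
    })
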