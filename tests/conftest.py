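import numpy as np
import pytest

import honeynmr as h


@pytest.fixture(scope="session")
def panel():
    return h.default_panel()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic two-class cohort (424 x 33, 105 positive)."""
    return h.simulate_cohort(h.CohortDesign(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
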