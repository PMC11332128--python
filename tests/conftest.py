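import numpy as np
import pytest

from suspicion.cues import add_cues
from suspicion.simulate import simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def exp1_cohort():
    """A moderate style-1 cohort (30 assessors x 90 trials) with cues attached."""
    return add_cues(simulate_study(1, seed=42, n_participants=30))


@pytest.fixture(scope="session")
def exp3_cohort():
    """A style-3 cohort (60 assessors x 60 trials, low/high stakes)."""
    return add_cues(simulate_study(3, seed=43, n_participants=60))
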