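import numpy as np
import pytest

from hstsim import Audiogram, ListenerModel
from hstsim.cohort import CohortConfig, generate_cohort


def make_det_listener(right=None, left=None) -> ListenerModel:
    """Ideal step-function listener from per-ear (500,1k,2k,4k) thresholds."""
    return ListenerModel(
        Audiogram.from_ear_levels(right=right, left=left), deterministic=True
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort (n=88) with stochastic listeners, seeded."""
    return generate_cohort(CohortConfig(n=88, seed=11))


@pytest.fixture(scope="session")
def det_cohort_small():
    """A 200-subject deterministic-listener cohort for pipeline tests."""
    return generate_cohort(CohortConfig(n=200, seed=5, listener_deterministic=True))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
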