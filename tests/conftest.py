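import numpy as np
import pytest

from flowpht import CohortConfig, ErlangMixtureSpec, simulate_cohort
from flowpht.synthetic_cohort import default_sojourn_specs


@pytest.fixture
def rng():
    return np.random.default_rng(20140507)


@pytest.fixture
def mixture_spec():
    """A generic three-component (1, 3, 5) mixture used across modules."""
    return ErlangMixtureSpec(
        weights=(0.5, 0.3, 0.2), rates=(0.6, 1.6, 2.2), shapes=(1, 3, 5)
    )


@pytest.fixture
def sojourn_specs():
    return default_sojourn_specs()


@pytest.fixture(scope="session")
def small_cohort():
    """A quickly simulated cohort with all three branches well populated."""
    config = CohortConfig(
        n_patients=600,
        p01=0.45,
        p02=0.20,
        p12=0.40,
        censor_rate=0.05,
        horizon=15.0,
        seed=7,
    )
    return simulate_cohort(config)
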