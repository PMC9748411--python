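import numpy as np
import pytest

import turtlebis as tb


@pytest.fixture(scope="session")
def default_phantom():
    """One full-geometry phantom with every false-positive class injected."""
    return tb.build_phantom(tb.PhantomSpec(seed=7, target_at_fraction=0.065))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """A cohort whose regression recovers the generating coefficients exactly."""
    return tb.generate_cohort(60, tb.CohortParams(nonat_noise_sd=0.0), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
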