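import numpy as np
import pytest

from catpain import CohortParams, make_template, simulate_cohort


@pytest.fixture(scope="session")
def template():
    return make_template((256, 256))


@pytest.fixture(scope="session")
def small_cohort(template):
    """A compact planted cohort (10 + 10 subjects) shared by fast tests."""
    params = CohortParams(n_per_class=10, seed=123)
    frame, sets = simulate_cohort(template, params)
    return params, frame, sets


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
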