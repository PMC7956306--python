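import numpy as np
import pytest
from hypothesis import settings

import ltcfactor as lf

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gm_params():
    return lf.GompertzMakehamParams(A=0.0002, B=3e-5, c=1.1, age_start=20, age_end=120)


@pytest.fixture(scope="session")
def gm_table(gm_params):
    return lf.make_base_table(gm_params)


@pytest.fixture(scope="session")
def spanish_pair(gm_params):
    """Synthetic (independent, dependent) pair under the Spanish men preset."""
    return lf.make_dependent_pair(gm_params, lf.SPAIN_SEVERE_MEN)


@pytest.fixture(scope="session")
def table3():
    return lf.fixture_table3()


@pytest.fixture
def toy_table():
    """Three-year table with q = (0.5, 0.5, 1): curtate e = 0.75 at age 0."""
    return lf.LifeTable(sex="male", cohort_year=1970, state="independent",
                        age_start=0, q=np.array([0.5, 0.5, 1.0]))
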