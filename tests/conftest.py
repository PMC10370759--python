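import numpy as np
import pytest
from hypothesis import settings

import sahcea as s
from sahcea.parameters import LifeTable, RebleedSchedule

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return s.default_parameters()


@pytest.fixture(scope="session")
def tm():
    return s.default_transition_fixture()


@pytest.fixture()
def immortal_life_table():
    """No background mortality until the closing age (far beyond stop_age)."""
    ages = np.arange(0, 201)
    qx = np.zeros(201)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


@pytest.fixture()
def no_rebleed_schedule():
    return RebleedSchedule(np.array([1]), np.array([0.0]), tail="constant")
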