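import numpy as np
import pytest

from petdosim import (
    ScanSchedule,
    default_kinetics,
    default_phantom,
    generate_cohort,
    icrp60_weights,
    synthetic_svalue_table,
)


@pytest.fixture(scope="session")
def schedule():
    return ScanSchedule()


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def svalues(phantom):
    return synthetic_svalue_table(phantom)


@pytest.fixture(scope="session")
def weights():
    return icrp60_weights()


@pytest.fixture(scope="session")
def cohort6(schedule):
    """A fixed six-subject cohort, as in the study."""
    return generate_cohort(6, seed=20210510, schedule=schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
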