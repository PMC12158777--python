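import pytest

import compositebias as cb


@pytest.fixture(scope="session")
def study_dag():
    return cb.ncds_dag()


@pytest.fixture(scope="session")
def default_scm():
    return cb.default_ncds_scenario()


@pytest.fixture(scope="session")
def cohort_5k(default_scm):
    """One medium cohort shared across read-only tests."""
    return cb.simulate(default_scm, cb.ScenarioConfig(n=5000, seed=11))
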