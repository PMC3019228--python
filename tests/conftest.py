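import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def case_study_fixture():
    from bionetkit import synth

    return synth.gen_case_study_fixture(seed=11)


@pytest.fixture(scope="session")
def regulatory_fixture():
    from bionetkit import synth

    return synth.gen_regulatory_fixture(seed=7)
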