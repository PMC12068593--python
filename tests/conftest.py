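import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")

from amblyref import builtin_criteria, default_targets, reconstruct_cohort


@pytest.fixture(scope="session")
def criteria():
    return builtin_criteria()


@pytest.fixture(scope="session")
def targets():
    return default_targets()


@pytest.fixture(scope="session")
def fixture_cohort_and_report(targets):
    """The deterministic study-scale fixture (built once per session)."""
    return reconstruct_cohort(targets)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_cohort_and_report):
    return fixture_cohort_and_report[0]


@pytest.fixture(scope="session")
def fixture_report(fixture_cohort_and_report):
    return fixture_cohort_and_report[1]
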