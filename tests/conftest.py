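import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

from yearscxr import reference_cohort, run_analysis  # noqa: E402


@pytest.fixture(scope="session")
def reference_records():
    return reference_cohort()


@pytest.fixture(scope="session")
def reference_report(reference_records):
    return run_analysis(reference_records)
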