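import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_cohort():
    """The deterministic synthetic cohort matching the published summaries."""
    from miascreen.study_data import build_reference_cohort

    return build_reference_cohort()


@pytest.fixture(scope="session")
def reference_calls(reference_cohort):
    """Per-patient test calls for every test on the reference cohort."""
    from miascreen.reporting_pipeline import classify_cohort

    return classify_cohort(reference_cohort)
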