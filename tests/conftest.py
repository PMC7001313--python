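import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def printed_cases():
    """Observation sets of the four worked high-VAF cases."""
    from masikit.io import load_printed_cases

    return load_printed_cases()


@pytest.fixture(scope="session")
def cohort_table():
    """The published 15-case cohort table."""
    from masikit.io import load_cohort_table

    return load_cohort_table()
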