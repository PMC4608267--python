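import pytest
from hypothesis import HealthCheck, settings

from ffmbia.subjects import Subject
from ffmbia.synthetic import CohortParams, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def table1_subject() -> Subject:
    """A subject at the published cohort means (Z derives to 509.1 Ω)."""
    return Subject(
        id="mean", sex="F", age=14.4, height_cm=166.0, weight_kg=94.3,
        resistance_ohm=505.2, reactance_ohm=62.6,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at the study size (n=103, seed 42)."""
    return generate_cohort(CohortParams(n=103, seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort for parameter-recovery checks (n=10000, seed 42)."""
    return generate_cohort(CohortParams(n=10_000, seed=42))
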