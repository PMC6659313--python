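import pytest
from hypothesis import HealthCheck, settings

from prestart import builtin_ruleset, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_cohort():
    """A seeded synthetic cohort at the study's country sizes (n=636)."""
    return generate_cohort(seed=20_19)


@pytest.fixture(scope="session")
def final_ruleset():
    return builtin_ruleset("final")


@pytest.fixture(scope="session")
def initial_ruleset():
    return builtin_ruleset("initial")
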