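import hypothesis
import pytest

from somnocohort import simulate

# reproducible property tests: fixed database-free derandomized profile
hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """Full synthetic bundle at desk scale (80 volunteers)."""
    return simulate.generate_cohort(simulate.SimConfig(n_volunteers=80, seed=7))


@pytest.fixture(scope="session")
def cohort_table():
    """Volunteer-level analysis table at the study's size."""
    return simulate.simulate_cohort_table(simulate.SimConfig(n_volunteers=482, seed=11))
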