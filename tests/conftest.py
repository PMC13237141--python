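import pytest

from loopbelief import (
    Attribution,
    CohortSpec,
    TaskConfig,
    sample_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


class ConstantAgent:
    """Rates a fixed value on every trial; attributes internally."""

    def __init__(self, rating: float = 50.0):
        self.rating = rating

    def expect(self, condition, trial_within):
        return self.rating

    def attribute(self, condition, trial_within, feedback, pe):
        return Attribution.INTERNAL

    def observe(self, condition, trial_within, feedback, attribution):
        pass


@pytest.fixture
def constant_agent_cls():
    return ConstantAgent


@pytest.fixture(scope="session")
def m5_session(task_config):
    """One synthetic M5 subject's full session (deterministic)."""
    profile = sample_cohort(CohortSpec(n_subjects=2, seed=11, sigma_range=(6.0, 6.0)))[0]
    return profile, simulate_subject(profile, task_config)


@pytest.fixture(scope="session")
def random_sessions(task_config):
    """A few synthetic sessions with mixed attributions, for property tests."""
    cohort = sample_cohort(CohortSpec(n_subjects=3, seed=23))
    return [simulate_subject(p, task_config) for p in cohort]
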