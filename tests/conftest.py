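import pytest
from hypothesis import settings

from pmflex import pm_cost, synthetic_cohort, task_design

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def session_design():
    return task_design.generate_session(6, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight simulated participants on a full 6-block session."""
    params = synthetic_cohort.SynthParams(n_participants=8, seed=101)
    probes, trials = synthetic_cohort.simulate_cohort(params)
    return probes, trials, params


@pytest.fixture(scope="session")
def trial_summary(small_cohort):
    probes, _, _ = small_cohort
    filtered = pm_cost.filter_responses(probes)
    summary, profiles = pm_cost.summarize_trials(filtered)
    return summary, profiles
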