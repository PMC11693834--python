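import numpy as np
import pandas as pd
import pytest

from lpexplore.coding import choice_events_dataset, code_dataset
from lpexplore.cohort import AgentPolicy, simulate_cohort
from lpexplore.learner import process_dataset
from lpexplore.models import build_choice_table


@pytest.fixture(scope="session")
def small_cohort():
    """20 simulated children, fixed 30-trial sessions, default study policy."""
    policy = AgentPolicy(session_rule="fixed", fixed_n_trials=30)
    trials, truth = simulate_cohort(20, policy, seed=123)
    return trials, truth


@pytest.fixture(scope="session")
def analysed_cohort(small_cohort):
    """Estimates + coding + choice table for the small cohort."""
    trials, truth = small_cohort
    est = code_dataset(process_dataset(trials))
    events = choice_events_dataset(est)
    perf = truth.performance_lookup()
    table = build_choice_table(est, events, perf, seed=123)
    return est, events, table, perf, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
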