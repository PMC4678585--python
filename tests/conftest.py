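import pytest

from periopcea import TrialDesign, generate_trial, uk_value_set


@pytest.fixture(scope="session")
def uk_vs():
    return uk_value_set()


@pytest.fixture(scope="session")
def small_trial():
    """A small synthetic trial with missingness, shared across tests."""
    return generate_trial(TrialDesign(n_per_arm=150, n_sites=5, seed=123))


@pytest.fixture(scope="session")
def complete_trial():
    """Same size trial with no missing EQ-5D among survivors."""
    return generate_trial(TrialDesign(n_per_arm=150, n_sites=5, seed=123,
                                      missing_prob_30d=0.0, missing_prob_6m=0.0))
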