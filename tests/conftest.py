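import pytest

from cvdms.synthetic import default_config, default_true_model, simulate_individuals


@pytest.fixture(scope="session")
def baseline_model():
    return default_true_model("baseline")


@pytest.fixture(scope="session")
def baseline_table(baseline_model):
    """Moderate baseline cohort shared by estimation-facing tests."""
    return simulate_individuals(
        baseline_model, default_config("baseline", n_persons=20_000, seed=42)
    )


@pytest.fixture(scope="session")
def baseline_probs(baseline_model):
    """True first-period transition probabilities of the baseline scenario."""
    return baseline_model.transition_probs("1996-2000")
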