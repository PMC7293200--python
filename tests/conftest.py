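import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reaction_set():
    """A deterministic batch of fixture reactions shared across tests."""
    from rvdesign.fixtures import FixtureSpec, generate_classified_reactions

    return generate_classified_reactions(FixtureSpec(n_reactions=120, seed=42))


@pytest.fixture(scope="session")
def pivoted_dataset(small_reaction_set):
    from rvdesign.dataset import build_labeled_entries, pivot_merge

    entries, _ = build_labeled_entries(small_reaction_set, level=3)
    return pivot_merge(entries, "maccs")


@pytest.fixture(scope="session")
def trained_cc_model(pivoted_dataset):
    from rvdesign.recommender import StrategyConfig, fit

    return fit(pivoted_dataset, StrategyConfig(strategy="cc", seed=11))
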