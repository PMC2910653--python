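import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def marsupial():
    """The packaged 21-taxon x 53-marker marsupial matrix."""
    from retromark.markers import load_marsupial_matrix

    return load_marsupial_matrix()


@pytest.fixture(scope="session")
def marsupial_search(marsupial):
    """Full replicated search on the packaged matrix (shared: it is the
    expensive step behind several tree-inference checks)."""
    from retromark.parsimony import SearchConfig, heuristic_search

    config = SearchConfig(n_random_additions=1000, swap="TBR", seed=17)
    trees, score = heuristic_search(marsupial, config)
    return trees, score


@pytest.fixture(scope="session")
def small_dataset():
    """A clean (perturbation-free) synthetic dataset at default settings."""
    from retromark import synth

    return synth.simulate(synth.default_config(seed=11))
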