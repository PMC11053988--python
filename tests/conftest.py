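import pytest

from nimo.fixtures import FixtureSpec, generate_fixture_set


@pytest.fixture(scope="session")
def fixture_set_small():
    """60 NP-like molecules; fast enough for per-module invariants."""
    return generate_fixture_set(FixtureSpec(n_molecules=60, seed=11))


@pytest.fixture(scope="session")
def fixture_set_full():
    """The seeded 1000-molecule set used by the round-trip benchmark."""
    return generate_fixture_set(FixtureSpec(n_molecules=1000, seed=42, stereo_fraction=0.3))


@pytest.fixture(scope="session")
def toy_corpus():
    from nimo.fixtures import generate_conditioned_toy_corpus

    return generate_conditioned_toy_corpus(seed=0, per_class=200)
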