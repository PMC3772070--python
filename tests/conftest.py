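import pytest

from smokestat import annotate_corpus, default_ruleset, generate_register
from smokestat.synthetic_data import SimulationConfig, make_fixture_suite


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def fixtures():
    return make_fixture_suite()


@pytest.fixture(scope="session")
def register():
    """Default-condition synthetic register shared across test modules."""
    return generate_register(SimulationConfig(n_patients=2000, seed=7))


@pytest.fixture(scope="session")
def annotations(register, rules):
    return annotate_corpus(register.documents, rules)
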