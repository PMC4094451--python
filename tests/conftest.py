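import pytest

from netview import (
    RandomModelSpec,
    build_network_graph,
    egfr_model,
    gprotein_model,
    random_model,
)


@pytest.fixture(scope="session")
def egfr():
    return egfr_model()


@pytest.fixture(scope="session")
def egfr_graph(egfr):
    return build_network_graph(egfr)


@pytest.fixture(scope="session")
def gprot():
    return gprotein_model()


@pytest.fixture(scope="session")
def gprot_graph(gprot):
    return build_network_graph(gprot)


@pytest.fixture
def make_random():
    def _make(seed: int, n_species: int = 5, n_rules: int = 8, **kw):
        return random_model(RandomModelSpec(
            n_species=n_species, n_rules=n_rules, seed=seed, **kw))
    return _make
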