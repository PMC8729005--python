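import numpy as np
import pytest

from pairpath import PartialCorrMatrix, RandomGGMConfig, random_ggm


@pytest.fixture
def three_node():
    """The worked 3-node example: pi_12=0.3, pi_13=0.4, pi_23=0.2."""
    return PartialCorrMatrix(
        ("a", "b", "c"),
        [[1.0, 0.3, 0.4], [0.3, 1.0, 0.2], [0.4, 0.2, 1.0]])


@pytest.fixture
def identity_p():
    return PartialCorrMatrix(("a", "b", "c"), np.eye(3))


@pytest.fixture
def chain4():
    """Chain a-b-c-d: one path per pair."""
    v = np.eye(4)
    for i, w in ((0, 0.5), (1, -0.4), (2, 0.3)):
        v[i, i + 1] = v[i + 1, i] = w
    return PartialCorrMatrix(("a", "b", "c", "d"), v)


@pytest.fixture
def model_factory():
    """Seeded random valid models: model_factory(n_nodes, seed, **kwargs)."""
    def make(n_nodes, seed, **kwargs):
        return random_ggm(RandomGGMConfig(n_nodes=n_nodes, seed=seed,
                                          **kwargs))
    return make


@pytest.fixture(scope="session")
def sim_model10():
    """The 10-node model used by the simulation-scale tests (10 edges,
    36 connected pairs, all fully enumerable within K=6)."""
    return random_ggm(RandomGGMConfig(n_nodes=10, seed=17))
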