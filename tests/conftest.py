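import numpy as np
import pytest

from endoloop.endocrine_sim import GlandNetwork, make_response
from endoloop.workbench import fixture_suite


@pytest.fixture
def decay_1g():
    """Single gland, pure first-order degradation at rate 1."""
    return GlandNetwork(["G"], np.zeros((1, 1)), np.array([1.0]))


@pytest.fixture
def linear_2g():
    net, _ = fixture_suite("linear_2g")
    return net


@pytest.fixture
def hpt_axis():
    net, _ = fixture_suite("hpt_axis")
    return net


@pytest.fixture
def random_hill_3g():
    """Three glands, mixed Hill/sigmoid secretion responses, fixed draw."""
    rng = np.random.default_rng(7)
    coupling = rng.uniform(-0.6, 0.6, size=(3, 3))
    np.fill_diagonal(coupling, 0.0)
    net = GlandNetwork(["X", "Y", "Z"], coupling, rng.uniform(0.2, 0.8, size=3))
    return net.with_source_responses([make_response("hill", K=1.0, n=2.0),
                                      make_response("sigmoid"),
                                      make_response("identity")])
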