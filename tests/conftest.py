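import numpy as np
import pytest

from hybridboss import fixtures as fx
from hybridboss.boolean_engine import InitialCondition, parse_network


@pytest.fixture
def cascade():
    return fx.make_cascade_model()


@pytest.fixture
def cascade_init():
    return fx.cascade_initial_condition()


@pytest.fixture
def fate():
    return fx.make_fate_model()


@pytest.fixture
def fate_init():
    return fx.fate_initial_condition()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toggle():
    """Two-state symmetric toggle: A flips ON<->OFF at unit rate."""
    bnd = """
    node A { logic = A; rate_up = 1; rate_down = 1; }
    """
    network, _ = parse_network(bnd)
    return network, InitialCondition({"A": 0.5})
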