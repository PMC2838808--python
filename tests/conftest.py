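import numpy as np
import pytest

from iterident.model_core import model_from_config, resting_state
from iterident.nfkb import build_nfkb_model


# --- toy model configurations used across the suite ---------------------

DECAY = {
    "name": "decay",
    "states": ["x"],
    "params": [{"name": "k", "value": 1.0, "free": True}],
    "rhs": {"x": "-k*x"},
    "observables": {"y": {"x": 1.0}},
    "initial": {"policy": "fixed", "seed": {"x": "2.0"}},
}

SUM_ONLY = {
    "name": "sum_only",
    "states": ["x"],
    "params": [{"name": "k1", "value": 1.0, "free": True},
               {"name": "k2", "value": 2.0, "free": True}],
    "rhs": {"x": "-(k1+k2)*x"},
    "observables": {"y": {"x": 1.0}},
    "initial": {"policy": "fixed", "seed": {"x": "1.0"}},
}

TWO_COMP = {
    "name": "two_comp",
    "states": ["x1", "x2"],
    "controls": ["u"],
    "params": [{"name": "k1", "value": 0.5, "free": True},
               {"name": "k2", "value": 0.3, "free": True}],
    "rhs": {"x1": "-k1*x1 + u", "x2": "k1*x1 - k2*x2"},
    "observables": {"y": {"x2": 1.0}},
    "initial": {"policy": "fixed", "seed": {"x1": "0", "x2": "0"}},
}

DECAY_GAIN = {
    "name": "decay_gain",
    "states": ["x"],
    "params": [{"name": "k", "value": 0.8, "free": True},
               {"name": "g", "value": 2.5, "free": True}],
    "rhs": {"x": "-k*x"},
    "observables": {"y": {"x": 1.0}},
    # gain enters through the initial condition
    "initial": {"policy": "fixed", "seed": {"x": "g"}},
}


def build(config, **kw):
    return model_from_config(config, **kw)


@pytest.fixture(scope="session")
def nfkb():
    model, space = build_nfkb_model()
    return model, space


@pytest.fixture(scope="session")
def nfkb_rest(nfkb):
    model, space = nfkb
    return resting_state(model, space.nominal)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
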