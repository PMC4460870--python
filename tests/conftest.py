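import numpy as np
import pytest

from aaflux.supply_fba import max_growth
from aaflux.synthetic_data import build_toy_model, toy1_spec, toy_aa_map


@pytest.fixture(scope="session")
def toy1():
    spec = toy1_spec()
    model = build_toy_model(spec)
    return spec, model, toy_aa_map(spec)


@pytest.fixture(scope="session")
def toy1_mu(toy1):
    _, model, _ = toy1
    return max_growth(model)


@pytest.fixture
def rng():
    return np.random.default_rng(20151113)
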