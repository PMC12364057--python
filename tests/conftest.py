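import numpy as np
import pytest
from hypothesis import settings

import manifoldmpc as mm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_glyphs():
    """A small labeled glyph set shared across tests."""
    return mm.generate_glyph_dataset(20, 10, seed=7)


@pytest.fixture(scope="session")
def tiny_circuit():
    """A 5-7-3 neuron circuit with noise disabled (deterministic)."""
    return mm.CircuitParams.random(layer_sizes=(5, 7, 3), input_dim=4,
                                   seed=3, eta=0.0, w_scale=2.0, r_scale=1.0)


@pytest.fixture(scope="session")
def default_fixture():
    return mm.LinearSpikingFixture.default(seed=0)
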