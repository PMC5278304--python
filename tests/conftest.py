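import numpy as np
import pytest

from ictonet import ModelParams, PlantedNetworkSpec, gen_planted_network


@pytest.fixture(scope="session")
def planted():
    """Default planted-focus network with its ground-truth focus."""
    C, focus = gen_planted_network(PlantedNetworkSpec(seed=11))
    return C, focus


@pytest.fixture()
def escape_params():
    """Parameters in a regime where an uncoupled node escapes within ~1e2
    time units (the default lam puts the barrier far above the noise)."""
    return ModelParams(lam=-0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
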