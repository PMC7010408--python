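import numpy as np
import pytest

from mcswim import ModelParams, build_swimmer


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def rest_state(default_params):
    return build_swimmer(default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def perturbed_state(params, scale_pos=0.02, scale_theta=0.2, seed=0):
    """A swimmer state pushed away from rest (for force/energy checks)."""
    state = build_swimmer(params)
    g = np.random.default_rng(seed)
    for f in range(2):
        state.bead_positions[f][1:] += scale_pos * g.standard_normal(
            state.bead_positions[f][1:].shape)
        state.theta[f] += scale_theta * g.standard_normal(len(state.theta[f]))
    return state
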