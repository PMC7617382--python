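import numpy as np
import pytest
from hypothesis import settings

from memscape import MEMParams, make_ground_truth
from memscape.model import PM1

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gt8():
    """Moderately coupled 8-region ground truth with exact structural match."""
    return make_ground_truth(8, coupling_scale=0.35, structure_noise=0.0, seed=5)


@pytest.fixture(scope="session")
def gt12():
    return make_ground_truth(12, coupling_scale=0.3, structure_noise=0.0, seed=7)


@pytest.fixture
def ferromagnet():
    def _make(n=6, j0=0.4, convention=PM1):
        J = j0 * (np.ones((n, n)) - np.eye(n))
        return MEMParams(h=np.zeros(n), J=J, convention=convention)

    return _make


@pytest.fixture
def random_params():
    def _make(n, scale=0.3, seed=0):
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n, k=1)
        J = np.zeros((n, n))
        J[iu] = rng.normal(0, scale, len(iu[0]))
        J = J + J.T
        return MEMParams(h=rng.uniform(-1, 0.5, n), J=J, convention=PM1)

    return _make
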