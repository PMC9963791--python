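import numpy as np
import pytest

from neurocalib.forward_models import HWNetwork
from neurocalib.hw_synthesis import cost_kernel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_hw_network(rng):
    """A hand-sized bipartite network with strictly positive costs."""
    n, m = 6, 4
    xo = rng.uniform(0, 1, (n, 2))
    xd = rng.uniform(0, 1, (m, 2))
    d = np.linalg.norm(xo[:, None, :] - xd[None, :, :], axis=-1)
    return HWNetwork(
        origin_sizes=rng.uniform(0.5, 1.5, n),
        cost_matrix=cost_kernel(d),
        initial_sizes=rng.uniform(0.3, 1.0, m),
    )
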