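import itertools

import numpy as np
import pytest

from scorebridge import FunctionDrift, ReplayBuffer, SDEConfig, simulate_em
from scipy.spatial.distance import cdist


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def w1_permutation_oracle(x, y):
    """Exhaustive minimisation over all permutation matchings (N <= 8)."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    assert x.shape == y.shape and x.shape[0] <= 8
    C = cdist(x, y)
    n = x.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        best = min(best, C[np.arange(n), perm].mean())
    return best


def stationary_ou_buffer(n_paths=512, n_steps=100, dt=0.01, theta=1.0,
                         sigma=1.0, seed=0, capacity=512):
    """Replay buffer of stationary OU trajectories (reverse drift = -x)."""
    rng = np.random.default_rng(seed)
    init_var = sigma ** 2 / (2 * theta)
    x0 = rng.normal(0.0, np.sqrt(init_var), size=(n_paths, 1))
    cfg = SDEConfig(sigma=sigma, dt=dt, n_steps=n_steps, dim=1)
    mu = FunctionDrift(lambda x, t: -theta * x, 1)
    ens = simulate_em(mu, x0, cfg, "forward", rng_seed=seed + 1)
    buf = ReplayBuffer(capacity)
    buf.push_ensemble(ens)
    return buf, mu
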