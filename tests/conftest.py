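import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_stable_closed_loop(N: int, tau: float, rng, margin: float = 0.1):
    """Random W_tilde whose closed-loop drift (W_tilde - I)/tau is stable."""
    G = rng.standard_normal((N, N)) / np.sqrt(N)
    lam_max = np.max(np.linalg.eigvals(G).real)
    # shift so max Re eig of (W - I)/tau equals -margin
    W = G + (1.0 - lam_max - margin * tau) * np.eye(N)
    return W


@pytest.fixture()
def stable_w_tilde(rng):
    return random_stable_closed_loop(10, 1.0, rng)
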