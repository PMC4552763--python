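import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(fun, x, h=1e-6):
    """Central-difference gradient of a scalar function of an (N, 3) array."""
    g = np.zeros_like(x)
    for a in range(len(x)):
        for d in range(3):
            xp = x.copy()
            xp[a, d] += h
            xm = x.copy()
            xm[a, d] -= h
            g[a, d] = (fun(xp) - fun(xm)) / (2 * h)
    return g


@pytest.fixture
def num_grad():
    return numeric_gradient
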