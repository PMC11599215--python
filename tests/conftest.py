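import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def coupled_pair(seed, n=256, rho=0.6):
    """White-noise pair with injected correlation rho."""
    g = np.random.default_rng(seed)
    x = g.standard_normal(n)
    e = g.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * e
    return x, y


@pytest.fixture
def eeg_grid():
    from mdc3 import FrequencyGrid

    return FrequencyGrid(0.5, 31.0, 0.5, 250.0)


@pytest.fixture
def fmri_grid():
    from mdc3 import FrequencyGrid

    return FrequencyGrid(0.01, 0.12, 0.01, 1.0)
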