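import numpy as np
import pytest

from mifreq import SinusoidModelParams, generate_dpss, simulate_random_sinusoids


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tapers128():
    """Default DPSS set (nw=2, K=3) for the default 128-sample geometry."""
    return generate_dpss(128, nw=2.0, n_tapers=3)


@pytest.fixture(scope="session")
def gp_paths_small():
    """200 paths of the Gaussian sinusoid pair at sigma_b=1 (truth ln 2)."""
    params = SinusoidModelParams(n_paths=200, sigma_b=1.0, seed=7)
    return simulate_random_sinusoids(params)
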