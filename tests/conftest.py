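import numpy as np
import pytest

from gaussmeta import make_toy_fixture, simulate_meta_ipd, DGMConfig


def random_fixture(seed: int):
    """A random valid IPD meta-analysis fixture with varying shape and scale."""
    rng = np.random.default_rng(seed)
    I = int(rng.integers(2, 8))
    specs = []
    for _ in range(I):
        n = int(rng.integers(5, 60))
        beta = float(rng.normal(0, 3))
        sigma2 = float(rng.uniform(0.2, 5.0))
        specs.append((n, beta, sigma2))
    return make_toy_fixture(specs, seed=seed)


@pytest.fixture
def toy_bundle():
    return make_toy_fixture([(20, 1.0, 1.0), (35, 0.5, 2.0), (11, 2.0, 0.5)], seed=1)


@pytest.fixture
def sim_bundle():
    return simulate_meta_ipd(DGMConfig(I=10, seed=42))
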