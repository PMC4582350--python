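import numpy as np
import pytest
import scipy.linalg as sl

from heritcomp.simulate import SimulationConfig, simulate_setting


@pytest.fixture(scope="session")
def setting1_small():
    """A small Setting-1 discovery/validation pair shared across unit tests."""
    cfg = SimulationConfig(seed=11, n=300, m=400)
    return simulate_setting(cfg)


@pytest.fixture(scope="session")
def small_grm(setting1_small):
    return setting1_small[0].grm


@pytest.fixture(scope="session")
def small_grm_eig(small_grm):
    d, U = sl.eigh(small_grm.G)
    return np.maximum(d, 0.0), U


def random_spd_pair(rng, d, jitter=0.1):
    """Random PSD A and SPD B of dimension d for optimizer tests."""
    M = rng.standard_normal((d + 2, d))
    A = M.T @ M / d
    N = rng.standard_normal((d + 3, d))
    B = N.T @ N / d + jitter * np.eye(d)
    return A, B
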