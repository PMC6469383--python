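import numpy as np
import pytest

from sgllmm.io import GroupStructure
from sgllmm.sgl import SGLProblem
from sgllmm.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured simulated panel shared across tests."""
    cfg = SimulationConfig(
        n_samples=150, n_groups=20, snps_per_group=10, sigma_sig=0.5,
        sigma_pop=0.7, seed=42,
    )
    return simulate_dataset(cfg)


def random_problem(rng, n=30, n_groups=3, group_size=3, alpha=0.95, scale_loss=True,
                   weights=None, snr=1.0):
    """A random small SGL instance with a planted sparse signal."""
    p = n_groups * group_size
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: group_size + 1] = rng.standard_normal(group_size + 1)
    y = X @ beta * snr + rng.standard_normal(n)
    groups = GroupStructure(
        [f"g{i}" for i in range(n_groups)], np.repeat(np.arange(n_groups), group_size)
    )
    return SGLProblem(X=X, y=y, groups=groups, alpha=alpha, scale_loss=scale_loss,
                      group_weights=weights)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
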