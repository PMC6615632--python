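import numpy as np
import pytest

import dfemix as dx


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated RL dataset with plates and fixed effects."""
    dfe = dx.DFESpec("multicategory", effects=(0.0, 0.3), frequencies=(0.6, 0.4))
    sc = dx.SimScenario(
        n_m=5, n_b=40, n_f=2, n_p=4, V_p=0.05, V_e=1.0,
        fixed_effect_sizes=(0.2, -0.1), seed=42,
    )
    data, truth = dx.simulate_rl_dataset(dfe, sc)
    return data, truth


def random_instance(rng, n_b=None, n_m=None, n_f=None, n_p=None):
    """A random small RLDataset for likelihood-oracle comparisons."""
    n_b = int(rng.integers(1, 21)) if n_b is None else n_b
    n_m = int(rng.integers(0, 6)) if n_m is None else n_m
    n_f = int(rng.integers(0, 3)) if n_f is None else n_f
    n_p = int(rng.integers(0, 4)) if n_p is None else n_p
    return dx.RLDataset(
        y=rng.normal(size=n_b),
        M=rng.integers(0, 2, size=(n_b, n_m)).astype(np.int8),
        F=rng.integers(0, 2, size=(n_b, n_f)).astype(np.int8),
        plate=rng.integers(0, n_p, size=n_b) if n_p else None,
        line=np.zeros(n_b, dtype=int),
    )
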