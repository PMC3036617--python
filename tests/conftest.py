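import numpy as np
import pandas as pd
import pytest

from zdimorph.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated two-species experiment."""
    cfg = SimConfig(n_ests=300, n_per_sex=3, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def medium_experiment():
    """Default study conditions at reduced EST count (shared across tests)."""
    cfg = SimConfig(n_ests=800, seed=42)
    return simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_expression(values, samples=None):
    """Small EST-by-sample log2 expression frame from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{j}" for j in range(m)]
    return pd.DataFrame(
        values, index=pd.Index([f"e{i}" for i in range(n)], name="est_id"), columns=samples
    )
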