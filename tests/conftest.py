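import numpy as np
import pandas as pd
import pytest

import margcrisk as mc

PI_SPEC = mc.PiModelSpec(features=("time", "z1", "z2"))


@pytest.fixture(scope="session")
def toy_dataset():
    """Tiny hand-checkable dataset: 3 clusters, 2 causes, one missing cause."""
    df = pd.DataFrame(
        {
            "cluster": ["a", "a", "b", "b", "c"],
            "time": [1.0, 2.0, 0.5, 1.5, 1.2],
            "delta": [1, 0, 1, 1, 1],
            "cause": [1, 0, 2, 0, 1],
            "r": [1, 1, 1, 0, 1],
            "z1": [0.5, -1.0, 0.3, 1.2, -0.7],
            "z2": [1.0, 0.0, 0.0, 1.0, 1.0],
        }
    )
    return mc.ClusteredDataset(df, z_cols=("z1", "z2"), n_causes=2)


@pytest.fixture(scope="session")
def sim_small():
    """One moderate scenario-1 dataset with missing causes (30 clusters)."""
    cfg = mc.ScenarioConfig(scenario=1, n_clusters=30, seed=101)
    return mc.generate(cfg)


@pytest.fixture(scope="session")
def sim_fit(sim_small):
    data, _ = sim_small
    return mc.fit_mpple(data, pi_spec=PI_SPEC)


@pytest.fixture(scope="session")
def singleton_data():
    """Independent subjects (all M_i = 1), no missing causes, two causes."""
    rng = np.random.default_rng(5)
    N = 300
    z1 = rng.normal(0, 1, N)
    z2 = rng.integers(0, 2, N).astype(float)
    t1 = rng.exponential(1, N) / np.exp(-0.5 * z1 + 0.3 * z2)
    t2 = rng.exponential(1.3, N) / np.exp(0.4 * z1)
    U = rng.exponential(2.0, N)
    T = np.minimum(t1, t2)
    lc = np.where(t1 <= t2, 1, 2)
    delta = (T <= U).astype(int)
    X = np.minimum(T, U)
    df = pd.DataFrame(
        {
            "cluster": np.arange(N),
            "time": X,
            "delta": delta,
            "cause": delta * lc,
            "r": 1,
            "z1": z1,
            "z2": z2,
        }
    )
    return mc.ClusteredDataset(df, z_cols=("z1", "z2"), n_causes=2)


@pytest.fixture(scope="session")
def singleton_fit(singleton_data):
    return mc.fit_mpple(singleton_data)
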