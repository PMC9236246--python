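import numpy as np
import pandas as pd
import pytest

import casecross as cc
from casecross.design import StratumSpec


@pytest.fixture(scope="session")
def small_dataset():
    """Two simulated years with a known CO effect at lag 1 (Poisson counts)."""
    params = cc.SimulationParams(
        n_days=731,
        start_date="2004-04-01",
        seed=42,
        baseline_rate=25.0,
        overdispersion=1.0,
        true_effects=(cc.Effect("CO", 1, 0.19),),
    )
    return cc.simulate(params)


@pytest.fixture(scope="session")
def small_counts(small_dataset):
    p = small_dataset.params
    end = pd.Timestamp(p.start_date) + pd.Timedelta(days=p.n_days - 1)
    return cc.build_counts(small_dataset.visits, p.start_date, end)


@pytest.fixture(scope="session")
def toy_design():
    """3 clusters, 14 days, exposure + one extra covariate; Poisson counts."""
    rng = np.random.default_rng(5)
    cluster = np.repeat([0, 1, 2], [5, 5, 4])
    X = rng.normal(size=(14, 2))
    alpha = np.array([1.0, 0.3, 0.7])
    y = rng.poisson(np.exp(0.3 * X[:, 0] - 0.2 * X[:, 1] + alpha[cluster]))
    return cc.DesignMatrix(X=X, y=y, cluster=cluster, names=("x", "z"))


@pytest.fixture
def all_stratum():
    return StratumSpec()
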