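import numpy as np
import pytest

from mixediou.iou_cov import IOUParams
from mixediou.model_core import LongDataset, VarianceParams, marginal_cov


def make_irregular_dataset(seed=7, m=12, q=1, alpha=2.0, omega=0.05, sigma_b2=0.12,
                           sigma2=0.04, beta=(4.6, -0.02)):
    """Small random-intercept IOU dataset with irregular visit times."""
    rng = np.random.default_rng(seed)
    G = np.array([[sigma_b2]]) if q == 1 else np.array([[sigma_b2, 0.01], [0.01, 0.02]])
    truth = VarianceParams(G, IOUParams(alpha, omega, "omega"), sigma2)
    ids, times, ys, Xs, Zs = [], [], [], [], []
    for i in range(m):
        n = int(rng.integers(2, 6))
        t = np.sort(rng.uniform(0, 20, n))
        X = np.column_stack([np.ones(n), t])
        Z = X[:, :q].copy()
        V = marginal_cov(t, truth, Z)
        y = X @ np.asarray(beta) + np.linalg.cholesky(V) @ rng.standard_normal(n)
        ids.append(i)
        times.append(t)
        ys.append(y)
        Xs.append(X)
        Zs.append(Z)
    return LongDataset(ids, times, ys, Xs, Zs, ["const", "time"]), truth


@pytest.fixture(scope="session")
def irregular_data():
    data, truth = make_irregular_dataset()
    return data


@pytest.fixture(scope="session")
def irregular_data_truth():
    return make_irregular_dataset()
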