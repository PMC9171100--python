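import numpy as np
import pytest

from pumice.annotate import PenaltyPartition


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def standardized(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


@pytest.fixture
def make_instance():
    """Random standardized regression instance with an essential split."""

    def _make(n=60, p=20, n_essential=8, h2=0.3, seed=0):
        r = np.random.default_rng(seed)
        X = standardized(r.standard_normal((n, p)))
        beta = np.zeros(p)
        k = max(2, p // 5)
        beta[r.choice(p, k, replace=False)] = r.normal(0, np.sqrt(h2 / k), k)
        y = X @ beta + r.normal(0, np.sqrt(1 - h2), n)
        y = y - y.mean()
        part = PenaltyPartition.from_mask(np.arange(p) < n_essential)
        return X, y, part

    return _make
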