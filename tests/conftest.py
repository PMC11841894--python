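import numpy as np
import pytest

import gcpca


@pytest.fixture(scope="session")
def fig1_truth():
    """Benchmark pair at n=1000, seed 0 (generated once per session)."""
    return gcpca.generate_fig1_dataset(1000, seed=0)


@pytest.fixture(scope="session")
def fig1_standardized(fig1_truth):
    """The benchmark pair after joint z-score + l2-norm standardization."""
    return gcpca.standardize_pair(fig1_truth.pair)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pair(seed: int, n: int = 20, p: int = 5) -> gcpca.ConditionPair:
    """A pair of independent standard-Gaussian condition matrices."""
    rng = np.random.default_rng(seed)
    return gcpca.ConditionPair(rng.normal(size=(n, p)), rng.normal(size=(n, p)))


def diagonal_pair(
    var_a=(4.0, 1.0), var_b=(1.0, 1.0), n: int = 40, seed: int = 7
) -> gcpca.ConditionPair:
    """A pair whose (uncentered) covariances are exactly diagonal.

    Columns are orthonormal vectors scaled so that ``D'D/(n-1)`` equals
    ``diag(var)`` exactly; fit with ``center=False`` to keep it exact.
    """
    rng = np.random.default_rng(seed)
    p = len(var_a)
    qa = np.linalg.qr(rng.normal(size=(n, p)))[0]
    qb = np.linalg.qr(rng.normal(size=(n, p)))[0]
    a = qa * np.sqrt(np.asarray(var_a) * (n - 1))
    b = qb * np.sqrt(np.asarray(var_b) * (n - 1))
    return gcpca.ConditionPair(a, b)
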