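import numpy as np
import pytest

from gomde import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_counts(rng):
    """A small random Poisson count matrix (8 cells x 5 genes)."""
    X = rng.poisson(2.0, size=(8, 5))
    X[0, 0] += 3  # ensure some variation
    return CountMatrix.from_array(X)


@pytest.fixture
def hard_two_group():
    """Two discrete groups of cells (binary memberships), K=2."""
    rng = np.random.default_rng(7)
    n = 40
    L = np.zeros((n, 2))
    L[: n // 2, 0] = 1.0
    L[n // 2 :, 1] = 1.0
    s = rng.integers(50, 150, size=n).astype(float)
    p_true = np.array([[0.05, 0.2], [0.1, 0.1], [0.3, 0.02]])  # 3 genes
    lam = s[:, None] * (L @ p_true.T)
    X = rng.poisson(lam)
    return X, L, s
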