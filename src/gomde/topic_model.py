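"""Poisson non-negative matrix factorization and the multinomial topic model.

The count matrix X (cells x features) is modelled as x_ij ~ Poisson(lambda_ij)
with the low-rank rate matrix Lambda = H W^T, H (n x K) and W (m x K)
non-negative.  This Poisson NMF model is equivalent, up to a simple
reparameterization, to the multinomial topic model

    x_i1, ..., x_im ~ Multinomial(s_i; pi_i1, ..., pi_im),   Pi = L F^T,

where s_i is the cell's total count, rows of L (membership proportions) sum
to 1 and columns of F (relative expression per topic) sum to 1.  Model
fitting maximizes the Poisson log-likelihood by monotone EM (multiplicative)
updates, optionally refined by cyclic coordinate ascent with per-coordinate
Newton steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

__all__ = [
    "CountMatrix",
    "PoissonNMFFit",
    "TopicModelFit",
    "fit_poisson_nmf",
    "poisson2multinom",
    "loglik",
    "kkt_residuals",
]

# rates are floored at this value inside update rules only; reported
# log-likelihoods use the unfloored rates
RATE_FLOOR = 1e-15

# parameters above this threshold are treated as interior points when
# classifying KKT residuals
KKT_POSITIVITY_THRESHOLD = 1e-10


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, n cells x m features.

    ``size_factors`` are the per-cell totals s_i = sum_j x_ij, the Poisson
    exposures of the model.
    """

    counts: sp.csr_matrix
    cell_ids: list
    feature_ids: list
    size_factors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        X = sp.csr_matrix(self.counts)
        if X.nnz:
            data = X.data
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        self.counts = X
        n, m = X.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"expected {n} cell ids, got {len(self.cell_ids)}")
        if len(self.feature_ids) != m:
            raise ValueError(
                f"expected {m} feature ids, got {len(self.feature_ids)}"
            )
        self.size_factors = np.asarray(X.sum(axis=1)).ravel().astype(float)

    @classmethod
    def from_array(cls, X, cell_ids=None, feature_ids=None) -> "CountMatrix":
        X = sp.csr_matrix(X)
        n, m = X.shape
        if cell_ids is None:
            cell_ids = [f"cell{i + 1}" for i in range(n)]
        if feature_ids is None:
            feature_ids = [f"gene{j + 1}" for j in range(m)]
        return cls(X, list(cell_ids), list(feature_ids))

    @property
    def shape(self):
        return self.counts.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)


@dataclass
class PoissonNMFFit:
    """Factor matrices of the Poisson NMF model, Lambda = H W^T."""

    H: np.ndarray  # n x K
    W: np.ndarray  # m x K
    K: int
    loglik_trace: np.ndarray
    method: str


@dataclass
class TopicModelFit:
    """Multinomial topic model: Pi = L F^T with simplex-constrained L, F."""

    L: np.ndarray  # n x K, rows sum to 1
    F: np.ndarray  # m x K, columns sum to 1
    topic_scales: np.ndarray  # column sums t_k of W used in the conversion
    fitted_sizes: np.ndarray  # per-cell scale s_i' from the conversion


def _as_dense_counts(X) -> np.ndarray:
    if isinstance(X, CountMatrix):
        return X.dense()
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def _poisson_loglik_core(X: np.ndarray, Lam: np.ndarray) -> float:
    """sum_ij x_ij log(lambda_ij) - lambda_ij, with 0 log 0 = 0."""
    mask = X > 0
    lam = Lam[mask]
    with np.errstate(divide="ignore"):
        terms = X[mask] * np.log(lam)
    return float(np.sum(terms) - np.sum(Lam))


def _em_update(X, H, W):
    """One EM sweep (update H, then W).  Monotone in the Poisson loglik."""
    Lam = np.maximum(H @ W.T, RATE_FLOOR)
    R = X / Lam
    H = H * (R @ W) / np.maximum(W.sum(axis=0), RATE_FLOOR)
    H = np.maximum(H, RATE_FLOOR)
    Lam = np.maximum(H @ W.T, RATE_FLOOR)
    R = X / Lam
    W = W * (R.T @ H) / np.maximum(H.sum(axis=0), RATE_FLOOR)
    W = np.maximum(W, RATE_FLOOR)
    return H, W


def _cd_update_column(X, A, B, k, Lam):
    """Coordinate-ascent update of column k of B, holding A fixed.

    The model here is X ~ Poisson(A B^T); because lambda_ij depends on b_jk
    only through row j, the coordinates b_1k..b_mk are mutually independent
    given the rest and can be updated simultaneously.  Each update is a
    projected Newton step with backtracking to guarantee ascent.
    """
    a = A[:, k]  # (n,)
    b = B[:, k]  # (m,)
    base = Lam - np.outer(a, b)
    base = np.maximum(base, 0.0)
    c = a.sum()

    lam = np.maximum(base + np.outer(a, b), RATE_FLOOR)
    ratio = X / lam
    grad = ratio.T @ a - c  # (m,)
    hess = -(X * (a**2)[:, None] / lam**2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        step = np.where(hess < 0, -grad / hess, np.where(grad < 0, -b, 0.0))
    b_new = np.maximum(b + step, RATE_FLOOR)

    # per-coordinate objective f_j(b) = sum_i x_ij log(base_ij + a_i b) - c b
    def obj(bv):
        lamv = np.maximum(base + np.outer(a, bv), RATE_FLOOR)
        out = np.zeros_like(bv)
        mask = X > 0
        with np.errstate(divide="ignore"):
            contrib = np.where(mask, X * np.log(lamv), 0.0)
        out = contrib.sum(axis=0) - c * bv
        return out

    f_old = obj(b)
    for _ in range(40):
        f_new = obj(b_new)
        bad = f_new < f_old - 1e-12
        if not np.any(bad):
            break
        b_new = np.where(bad, 0.5 * (b_new + b), b_new)
    else:
        b_new = np.where(obj(b_new) < f_old - 1e-12, b, b_new)

    B = B.copy()
    B[:, k] = b_new
    Lam = base + np.outer(a, b_new)
    return B, Lam


def _cd_update(X, H, W):
    """One full cyclic coordinate-ascent sweep over columns of W then H."""
    Lam = H @ W.T
    K = W.shape[1]
    for k in range(K):
        W, Lam = _cd_update_column(X, H, W, k, Lam)
    LamT = Lam.T
    for k in range(K):
        H, LamT = _cd_update_column(X.T, W, H, k, LamT)
    return H, W


def _random_init(X, K, rng):
    """Gamma(1,1) entries scaled so the fitted rates match the data scale."""
    n, m = X.shape
    H = rng.gamma(1.0, 1.0, size=(n, K)) + RATE_FLOOR
    W = rng.gamma(1.0, 1.0, size=(m, K)) + RATE_FLOOR
    # scale rows of H to the cell totals and columns of W to unit sums so
    # that Lambda has approximately the right row sums
    s = X.sum(axis=1)
    H = H / H.sum(axis=1, keepdims=True) * np.maximum(s, RATE_FLOOR)[:, None]
    W = W / W.sum(axis=0, keepdims=True)
    return H, W


def fit_poisson_nmf(
    X,
    K: int,
    method: str = "cd",
    numiter_prefit: int = 1000,
    numiter_refine: int = 1000,
    init: str = "random",
    seed: int = 1,
    H0: np.ndarray | None = None,
    W0: np.ndarray | None = None,
    update_H: bool = True,
) -> PoissonNMFFit:
    """Fit the Poisson NMF model by monotone ascent.

    A prefit phase of ``numiter_prefit`` EM updates is followed by
    ``numiter_refine`` updates of the requested ``method`` ("em" or "cd").
    The Poisson log-likelihood (without the factorial constant) is recorded
    after every iteration and is non-decreasing.  ``update_H=False`` holds H
    fixed and fits W only (used when memberships are known).
    """
    Xd = _as_dense_counts(X)
    if np.any(Xd < 0) or not np.allclose(Xd, np.round(Xd)):
        raise ValueError("counts must be non-negative integers")
    n, m = Xd.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds min(n, m)={min(n, m)}")
    if Xd.sum() == 0:
        raise ValueError("all-zero count matrix is degenerate")
    if method not in ("em", "cd"):
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    if init == "custom":
        if H0 is None or W0 is None:
            raise ValueError("init='custom' requires H0 and W0")
        H = np.maximum(np.asarray(H0, dtype=float).copy(), RATE_FLOOR)
        W = np.maximum(np.asarray(W0, dtype=float).copy(), RATE_FLOOR)
        if H.shape != (n, K) or W.shape != (m, K):
            raise ValueError("H0/W0 have the wrong shape")
    else:
        H, W = _random_init(Xd, K, rng)

    trace = [_poisson_loglik_core(Xd, H @ W.T)]
    for _ in range(numiter_prefit):
        if update_H:
            H, W = _em_update(Xd, H, W)
        else:
            _, W = _em_update_W_only(Xd, H, W)
        trace.append(_poisson_loglik_core(Xd, H @ W.T))
    for _ in range(numiter_refine):
        if method == "em":
            if update_H:
                H, W = _em_update(Xd, H, W)
            else:
                _, W = _em_update_W_only(Xd, H, W)
        else:
            if update_H:
                H, W = _cd_update(Xd, H, W)
            else:
                Lam = H @ W.T
                for k in range(K):
                    W, Lam = _cd_update_column(Xd, H, W, k, Lam)
        trace.append(_poisson_loglik_core(Xd, H @ W.T))

    return PoissonNMFFit(
        H=H, W=W, K=K, loglik_trace=np.asarray(trace), method=method
    )


def _em_update_W_only(X, H, W):
    Lam = np.maximum(H @ W.T, RATE_FLOOR)
    R = X / Lam
    W = W * (R.T @ H) / np.maximum(H.sum(axis=0), RATE_FLOOR)
    return H, np.maximum(W, RATE_FLOOR)


def poisson2multinom(fit: PoissonNMFFit) -> TopicModelFit:
    """Recover the topic model (L, F) from a Poisson NMF fit (H, W).

    With t_k = sum_j w_jk: f_jk = w_jk / t_k, l~_ik = h_ik t_k,
    s_i' = sum_k l~_ik and l_ik = l~_ik / s_i'.  The rescaling satisfies
    diag(s') L F^T = H W^T exactly.
    """
    W = np.asarray(fit.W, dtype=float)
    H = np.asarray(fit.H, dtype=float)
    t = W.sum(axis=0)
    zero = np.nonzero(t == 0)[0]
    if zero.size:
        raise ValueError(f"topic {zero[0] + 1} has an all-zero column in W")
    F = W / t
    Lt = H * t
    s = Lt.sum(axis=1)
    L = Lt / np.maximum(s, RATE_FLOOR)[:, None]
    return TopicModelFit(L=L, F=F, topic_scales=t, fitted_sizes=s)


def loglik(X, fit) -> tuple[np.ndarray, float]:
    """Per-cell log-likelihood and its total.

    For a :class:`PoissonNMFFit` this is the Poisson log-likelihood
    sum_j [x log(lambda) - lambda - log(x!)]; for a :class:`TopicModelFit`
    the multinomial log-likelihood with cell probabilities pi_i.  Rates of
    zero where x > 0 yield -inf rather than an exception.
    """
    Xd = _as_dense_counts(X)
    if isinstance(fit, PoissonNMFFit):
        Lam = fit.H @ fit.W.T
        if Lam.shape != Xd.shape:
            raise ValueError("fit dimensions do not match the counts")
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.where(Xd > 0, Xd * np.log(Lam), 0.0)
        lx = np.where((Xd > 0) & (Lam == 0), -np.inf, lx)
        per_cell = np.sum(lx - Lam - gammaln(Xd + 1), axis=1)
    elif isinstance(fit, TopicModelFit):
        Pi = fit.L @ fit.F.T
        if Pi.shape != Xd.shape:
            raise ValueError("fit dimensions do not match the counts")
        s = Xd.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.where(Xd > 0, Xd * np.log(Pi), 0.0)
        lx = np.where((Xd > 0) & (Pi == 0), -np.inf, lx)
        per_cell = (
            gammaln(s + 1) - gammaln(Xd + 1).sum(axis=1) + lx.sum(axis=1)
        )
    else:
        raise TypeError("fit must be a PoissonNMFFit or TopicModelFit")
    return per_cell, float(per_cell.sum())


def kkt_residuals(X, fit: PoissonNMFFit) -> dict:
    """Max-norm residuals of the KKT first-order conditions for W and H.

    The gradient of the negative log-likelihood with respect to w_jk is
    g_jk = sum_i h_ik (1 - x_ij / lambda_ij).  At an interior coordinate
    (parameter > threshold) the residual is |g|; at the boundary it is
    max(0, -g).  Residuals vanish at a maximum-likelihood solution.
    """
    Xd = _as_dense_counts(X)
    H, W = fit.H, fit.W
    Lam = np.maximum(H @ W.T, RATE_FLOOR)
    R = 1.0 - Xd / Lam
    GW = R.T @ H  # m x K, gradient of negative loglik wrt W
    GH = R @ W  # n x K
    resW = np.where(
        W > KKT_POSITIVITY_THRESHOLD, np.abs(GW), np.maximum(0.0, -GW)
    )
    resH = np.where(
        H > KKT_POSITIVITY_THRESHOLD, np.abs(GH), np.maximum(0.0, -GH)
    )
    return {
        "W": float(resW.max()),
        "H": float(resH.max()),
        "W_residuals": resW,
        "H_residuals": resH,
    }
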