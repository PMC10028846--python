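"""Grade-of-membership differential expression (GoM DE).

For one gene j with counts x_1j..x_nj, exposures s_i and known membership
proportions l_i1..l_iK, the model is

    x_ij ~ Poisson(s_i * theta_ij),    theta_ij = sum_k l_ik p_jk,

where p_j1..p_jK are the unknown relative expression rates.  Each rate gets
a Gamma(1 + eps, 1) prior; MAP estimation under that prior is equivalent to
maximum likelihood on data augmented with K pseudo-observations of count
eps, exposure 1 and identity memberships.  Uncertainty in log-fold-change
(LFC) statistics derived from the rates is quantified by a single-coordinate
random-walk Metropolis sampler on g_jk = log p_jk: a topic is chosen
uniformly at random, a Gaussian step of sd sigma is proposed on the log
scale, and the move is accepted with probability

    min(1, likelihood-ratio * p*_k / p_k),

the extra factor being the Jacobian of the log parameterization.  The LFC
statistic is evaluated per MCMC sample and summarized by its posterior
mean, a highest-posterior-density (HPD) interval and an asymmetric
standard-error rule; estimates are then optionally stabilized across genes
by empirical-Bayes adaptive shrinkage.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .shrinkage import adaptive_shrink

__all__ = [
    "GoMDEOptions",
    "GeneRates",
    "MCMCChain",
    "PosteriorSummary",
    "GoMDEResult",
    "fit_null",
    "fit_gom_map",
    "fit_gom_map_all",
    "pairwise_lfc",
    "le_lfc",
    "null_lfc",
    "mcmc_gene",
    "hpd_interval",
    "summarize_posterior",
    "de_analysis",
]

_LN2 = math.log(2.0)


@dataclass
class GoMDEOptions:
    """Tuning parameters of the GoM DE analysis.

    pseudocount: eps of the Gamma(1 + eps, 1) prior (default 0.1).
    ns: Markov-chain length (default 10,000; 100,000 for final runs).
    proposal_sd: sd sigma of the Gaussian random-walk proposal (default 0.3).
    hpd_level: HPD mass 1 - alpha (default 0.68, so the asymmetric SE rule
        recovers a conventional standard error for near-Gaussian posteriors).
    lfc_stat: "le" (least extreme), "vsnull", or "pairwise" with ref_topic.
    """

    pseudocount: float = 0.1
    ns: int = 10_000
    proposal_sd: float = 0.3
    hpd_level: float = 0.68
    lfc_stat: str = "le"
    ref_topic: int | None = None
    seed: int = 1
    threads: int = 1
    shrink: bool = True
    burn_in: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.ns < 1:
            raise ValueError("ns must be >= 1")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")
        if not 0 < self.hpd_level < 1:
            raise ValueError("hpd_level must be in (0, 1)")
        if self.lfc_stat not in ("le", "vsnull", "pairwise"):
            raise ValueError(f"unknown lfc_stat {self.lfc_stat!r}")
        if self.lfc_stat == "pairwise" and self.ref_topic is None:
            raise ValueError("lfc_stat='pairwise' requires ref_topic")


@dataclass
class GeneRates:
    """Relative expression rates for one gene: p_1..p_K and the null rate."""

    p: np.ndarray
    p0: float


@dataclass
class MCMCChain:
    """Sampled log-rate states g (ns x K) and the acceptance fraction."""

    g: np.ndarray
    accept_rate: float
    seed: object = None


@dataclass
class PosteriorSummary:
    """Per-topic posterior summaries of the chosen LFC statistic."""

    postmean: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    se: np.ndarray
    n_excluded: np.ndarray  # infinite per-sample statistics dropped per topic


@dataclass
class GoMDEResult:
    """Tables (genes x topics) of posterior LFC statistics."""

    feature_ids: list
    postmean_lfc: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    se: np.ndarray
    shrunk_lfc: np.ndarray
    shrunk_se: np.ndarray
    zscore: np.ndarray
    lfsr: np.ndarray
    svalue: np.ndarray
    pvalue: np.ndarray
    p0: np.ndarray
    f_map: np.ndarray
    options: GoMDEOptions
    flagged: np.ndarray = field(default=None)

    @property
    def K(self) -> int:
        return self.postmean_lfc.shape[1]


def _check_counts(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    return x


def fit_null(x, s, pseudocount: float = 0.0) -> float:
    """MLE (eps = 0) or MAP (eps > 0) of the constant null rate p_j0.

    With eps = 0 this is exactly sum(x) / sum(s); with eps > 0 the single
    pseudo-observation of the augmented problem gives (sum(x) + eps) /
    (sum(s) + 1).
    """
    x = _check_counts(x)
    s = np.asarray(s, dtype=float)
    if x.shape != s.shape:
        raise ValueError("x and s must have the same length")
    if s.sum() <= 0:
        raise ValueError("total exposure must be positive")
    if pseudocount == 0:
        return float(x.sum() / s.sum())
    return float((x.sum() + pseudocount) / (s.sum() + 1.0))


def _augment(x, L, s, eps):
    """Append the K pseudo-observations implementing the Gamma prior."""
    K = L.shape[1]
    x_aug = np.concatenate([x, np.full(K, eps)])
    L_aug = np.vstack([L, np.eye(K)])
    s_aug = np.concatenate([s, np.ones(K)])
    return x_aug, L_aug, s_aug


def _check_memberships(L):
    L = np.asarray(L, dtype=float)
    rs = L.sum(axis=1)
    if np.any(np.abs(rs - 1.0) > 1e-6):
        raise ValueError("membership rows must sum to 1")
    return L


def fit_gom_map_all(
    X,
    L,
    s,
    pseudocount: float = 0.1,
    tol: float = 1e-8,
    maxiter: int = 1000,
):
    """MAP rates for all genes at once (m x K), plus convergence flags.

    The MAP under Gamma(1 + eps, 1) priors equals the MLE of the augmented
    problem; with memberships fixed the multiplicative Poisson NMF update of
    W applies column-wise and is monotone in the augmented log-posterior.
    """
    X = np.asarray(X, dtype=float)
    L = _check_memberships(L)
    s = np.asarray(s, dtype=float)
    n, m = X.shape
    K = L.shape[1]
    X_aug = np.vstack([X, np.full((K, m), float(pseudocount))])
    L_aug = np.vstack([L, np.eye(K)])
    s_aug = np.concatenate([s, np.ones(K)])
    H = s_aug[:, None] * L_aug  # (n + K) x K, fixed
    b = H.sum(axis=0)  # column exposures, sum_i s_i l_ik + 1

    # initialize every gene at its augmented null rate
    p_init = (X_aug.sum(axis=0)) / (s.sum() + K)
    P = np.tile(np.maximum(p_init, 1e-300)[:, None], (1, K))

    converged = np.zeros(m, dtype=bool)
    for _ in range(maxiter):
        Lam = np.maximum(H @ P.T, 1e-300)  # (n + K) x m
        P_new = P * ((X_aug / Lam).T @ H) / b
        delta = np.max(
            np.abs(P_new - P) / np.maximum(np.abs(P), 1e-300), axis=1
        )
        P = P_new
        converged |= delta < tol
        if np.all(delta < tol):
            break
    return P, converged


def fit_gom_map(
    x,
    L,
    s,
    pseudocount: float = 0.1,
    tol: float = 1e-10,
    maxiter: int = 10_000,
) -> GeneRates:
    """MAP estimate of one gene's rates p_1..p_K (see fit_gom_map_all)."""
    x = _check_counts(x)
    P, converged = fit_gom_map_all(
        x[:, None], L, s, pseudocount=pseudocount, tol=tol, maxiter=maxiter
    )
    if not converged[0]:
        import warnings

        warnings.warn("fit_gom_map did not converge; best iterate returned")
    p0 = fit_null(x, s, pseudocount)
    return GeneRates(p=P[0], p0=p0)


def pairwise_lfc(p: GeneRates | np.ndarray, k: int, l: int) -> float:
    """Base-2 log fold change log2(p_k / p_l); 0/0 is defined as 0."""
    pv = p.p if isinstance(p, GeneRates) else np.asarray(p, dtype=float)
    pk, pl = pv[k], pv[l]
    if pk == 0 and pl == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(np.log2(pk) - np.log2(pl))


def le_lfc(p: GeneRates | np.ndarray, k: int) -> float:
    """Least extreme LFC for topic k: the pairwise LFC against the other
    topic yielding the smallest absolute change (ties broken by the lowest
    comparison-topic index).  Reduces to the standard LFC when K = 2."""
    pv = p.p if isinstance(p, GeneRates) else np.asarray(p, dtype=float)
    K = pv.size
    if K < 2:
        raise ValueError("least extreme LFC is undefined for K = 1")
    lfcs = np.array(
        [pairwise_lfc(pv, k, l) for l in range(K) if l != k]
    )
    return float(lfcs[np.argmin(np.abs(lfcs))])


def le_lfc_table(F) -> np.ndarray:
    """Least extreme LFCs for every (gene, topic) of a rates table (m x K)."""
    F = np.asarray(F, dtype=float)
    m, K = F.shape
    out = np.empty((m, K))
    for k in range(K):
        out[:, k] = [le_lfc(F[j], k) for j in range(m)]
    return out


def null_lfc(p: GeneRates | np.ndarray, k: int, p0: float | None = None):
    """LFC of topic k versus the constant null model: log2(p_k / p_0)."""
    if isinstance(p, GeneRates):
        pv, p0v = p.p, p.p0
    else:
        pv, p0v = np.asarray(p, dtype=float), p0
    if p0v is None:
        raise ValueError("p0 is required")
    if p0v == 0 and pv[k] == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(np.log2(pv[k]) - np.log2(p0v))


# ---------------------------------------------------------------------------
# Random-walk Metropolis sampler
# ---------------------------------------------------------------------------

def _mh_kernel_py(
    g, p, theta, xs, Lnz, act_idx, act_off, b, eps,
    topics, deltas, logu, chain,
):
    """Single-coordinate random-walk Metropolis on g = log p.

    ``theta`` holds sum_k l_ik p_k for the cells with nonzero counts only;
    the Poisson -s*theta term enters through the precomputed column
    exposures ``b`` and the eps pseudo-observations contribute
    eps * log(p_k) - p_k analytically, so each step touches only the
    nonzero-count cells with nonzero membership in the proposed topic.
    """
    ns = topics.shape[0]
    K = g.shape[0]
    accepted = 0
    for t in range(ns):
        k = topics[t]
        d = deltas[t]
        pk = p[k]
        pk_new = pk * math.exp(d)
        dp = pk_new - pk
        dll = -b[k] * dp + eps * d
        ok = True
        for ii in range(act_off[k], act_off[k + 1]):
            i = act_idx[ii]
            th_new = theta[i] + Lnz[i, k] * dp
            if th_new <= 0.0:
                ok = False
                break
            dll += xs[i] * (math.log(th_new) - math.log(theta[i]))
        # accept with probability min(1, exp(dll + d)); d is the Jacobian
        if ok and dll == dll and logu[t] <= dll + d:
            p[k] = pk_new
            g[k] = g[k] + d
            for ii in range(act_off[k], act_off[k + 1]):
                i = act_idx[ii]
                theta[i] = theta[i] + Lnz[i, k] * dp
            accepted += 1
        for kk in range(K):
            chain[t, kk] = g[kk]
    return accepted


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _mh_kernel = njit(cache=True, nogil=True)(_mh_kernel_py)
except ImportError:  # pragma: no cover
    _mh_kernel = _mh_kernel_py


def acceptance_probability(x, L, s, g_current, k, g_proposed_k, eps=0.0):
    """Acceptance probability of a single proposed move (reference form).

    Evaluates min(1, Pr(x | p*) / Pr(x | p) * p*_k / p_k) directly from the
    Poisson likelihood over the augmented data; used as an oracle for the
    incremental kernel computation.
    """
    x = _check_counts(x)
    L = _check_memberships(L)
    s = np.asarray(s, dtype=float)
    x_aug, L_aug, s_aug = _augment(x, L, s, eps)
    p_cur = np.exp(np.asarray(g_current, dtype=float))
    p_new = p_cur.copy()
    p_new[k] = math.exp(g_proposed_k)

    def ll(p):
        lam = s_aug * (L_aug @ p)
        with np.errstate(divide="ignore"):
            terms = np.where(x_aug > 0, x_aug * np.log(lam), 0.0)
        return float(terms.sum() - lam.sum())

    log_ratio = ll(p_new) - ll(p_cur) + math.log(p_new[k] / p_cur[k])
    return min(1.0, math.exp(log_ratio))


def mcmc_gene(x, L, s, g0, options: GoMDEOptions, rng=None) -> MCMCChain:
    """Simulate the random-walk Metropolis chain for one gene.

    Randomness is pre-generated from ``rng`` (or ``options.seed``) so the
    chain is reproducible and independent of the execution backend.
    """
    x = _check_counts(x)
    L = _check_memberships(L)
    s = np.asarray(s, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    if not np.all(np.isfinite(g0)):
        raise ValueError("initial log-rates must be finite")
    if rng is None:
        rng = np.random.default_rng(options.seed)
    K = L.shape[1]
    eps = float(options.pseudocount)

    nz = np.nonzero(x)[0]
    xs = x[nz].astype(float)
    Lnz = np.ascontiguousarray(L[nz, :], dtype=float)
    b = s @ L + 1.0  # augmented column exposures
    act_lists = [np.nonzero(Lnz[:, k] > 0)[0] for k in range(K)]
    act_off = np.zeros(K + 1, dtype=np.int64)
    act_off[1:] = np.cumsum([a.size for a in act_lists])
    act_idx = (
        np.concatenate(act_lists).astype(np.int64)
        if nz.size
        else np.zeros(0, dtype=np.int64)
    )

    ns = options.ns
    topics = rng.integers(0, K, size=ns).astype(np.int64)
    deltas = rng.normal(0.0, options.proposal_sd, size=ns)
    logu = np.log(rng.random(size=ns))

    g = g0.copy()
    p = np.exp(g)
    theta = Lnz @ p if nz.size else np.zeros(0)
    if nz.size and np.any(theta <= 0):
        raise ValueError("non-finite likelihood at the initial state")
    chain = np.empty((ns, K))
    accepted = _mh_kernel(
        g, p, theta, xs, Lnz, act_idx, act_off, b, eps,
        topics, deltas, logu, chain,
    )
    if options.burn_in or options.thin > 1:
        chain = chain[options.burn_in :: options.thin]
    return MCMCChain(g=chain, accept_rate=accepted / ns, seed=None)


def hpd_interval(samples, level: float):
    """Smallest interval of consecutive order statistics holding ``level``
    of the samples; ties broken by the earliest window."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    nsamp = x.size
    if nsamp < 2:
        raise ValueError("need at least 2 samples")
    w = int(math.ceil(level * nsamp))
    w = min(max(w, 1), nsamp)
    widths = x[w - 1 :] - x[: nsamp - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def _lfc_samples(G: np.ndarray, k: int, options: GoMDEOptions, log_p0=None):
    """The chosen LFC statistic evaluated at every MCMC sample."""
    stat = options.lfc_stat
    if stat == "le":
        K = G.shape[1]
        if K < 2:
            raise ValueError("least extreme LFC is undefined for K = 1")
        diffs = (G[:, [k]] - np.delete(G, k, axis=1)) / _LN2
        pick = np.argmin(np.abs(diffs), axis=1)
        return diffs[np.arange(diffs.shape[0]), pick]
    if stat == "vsnull":
        if log_p0 is None:
            raise ValueError("vsnull statistic requires the null rate")
        return (G[:, k] - log_p0) / _LN2
    if stat == "pairwise":
        ref = options.ref_topic
        if k == ref:
            return np.zeros(G.shape[0])
        return (G[:, k] - G[:, ref]) / _LN2
    raise ValueError(f"unknown lfc_stat {stat!r}")


def summarize_posterior(
    chain: MCMCChain, options: GoMDEOptions, log_p0=None
) -> PosteriorSummary:
    """Posterior mean, HPD interval and asymmetric SE per topic.

    The statistic is computed per MCMC sample and then averaged (never the
    statistic of the posterior-mean rates).  The SE follows the asymmetric
    rule s = b - mean when mean < 0, else mean - a, which prevents
    over-shrinking of estimates whose interval barely overlaps zero.
    Non-finite per-sample values are excluded and counted.
    """
    G = chain.g
    ns, K = G.shape
    postmean = np.empty(K)
    lo = np.empty(K)
    hi = np.empty(K)
    se = np.empty(K)
    nexcl = np.zeros(K, dtype=int)
    for k in range(K):
        beta = _lfc_samples(G, k, options, log_p0=log_p0)
        finite = np.isfinite(beta)
        nexcl[k] = int((~finite).sum())
        bs = beta[finite]
        if bs.size == 0:
            postmean[k] = np.nan
            lo[k] = hi[k] = np.nan
            se[k] = np.nan
            continue
        m = float(bs.mean())
        if bs.size >= 2 and bs.max() > bs.min():
            a, b = hpd_interval(bs, options.hpd_level)
        else:
            a = b = float(bs[0])
        postmean[k] = m
        lo[k], hi[k] = a, b
        se[k] = (b - m) if m < 0 else (m - a)
        se[k] = max(se[k], 0.0)
    return PosteriorSummary(
        postmean=postmean, hpd_lower=lo, hpd_upper=hi, se=se, n_excluded=nexcl
    )


def _gene_seed_sequence(base_seed: int, gene_index: int):
    """Deterministic per-gene RNG stream, independent of thread count."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(gene_index,))
    )


def de_analysis(
    X, L, options: GoMDEOptions | None = None, size_factors=None
) -> GoMDEResult:
    """Run the full GoM DE analysis: MAP fit, per-gene MCMC, posterior
    summaries and (optionally) adaptive shrinkage across genes per topic.

    Per-gene seeds derive deterministically from (base seed, gene index),
    so results do not depend on ``threads``.  HPD bounds are reported on
    the raw (pre-shrinkage) scale.  ``size_factors`` defaults to the cell
    totals of ``X``; pass them explicitly when analyzing a subset of genes
    so the exposures still reflect the full transcriptome.
    """
    from .topic_model import CountMatrix

    if options is None:
        options = GoMDEOptions()
    if isinstance(X, CountMatrix):
        Xd = X.dense()
        feature_ids = list(X.feature_ids)
        s = X.size_factors
    else:
        Xd = np.asarray(X, dtype=float)
        feature_ids = [f"gene{j + 1}" for j in range(Xd.shape[1])]
        s = Xd.sum(axis=1)
    if size_factors is not None:
        s = np.broadcast_to(
            np.asarray(size_factors, dtype=float), (Xd.shape[0],)
        ).copy()
    L = _check_memberships(L)
    n, m = Xd.shape
    if L.shape[0] != n:
        raise ValueError("L must have one row per cell")
    K = L.shape[1]
    eps = float(options.pseudocount)

    P_map, converged = fit_gom_map_all(Xd, L, s, pseudocount=eps)
    colsum = Xd.sum(axis=0)
    p0_raw = colsum / s.sum()
    p0_aug = (colsum + eps) / (s.sum() + 1.0)
    zero_genes = colsum == 0

    postmean = np.empty((m, K))
    lo = np.empty((m, K))
    hi = np.empty((m, K))
    se = np.empty((m, K))
    nexcl = np.zeros((m, K), dtype=int)
    accept = np.empty(m)

    def run_gene(j):
        rng = _gene_seed_sequence(options.seed, j)
        g0 = np.log(np.maximum(P_map[j], 1e-300))
        chain = mcmc_gene(Xd[:, j], L, s, g0, options, rng=rng)
        log_p0 = math.log(p0_aug[j]) if p0_aug[j] > 0 else -np.inf
        summ = summarize_posterior(chain, options, log_p0=log_p0)
        return j, summ, chain.accept_rate

    if options.threads > 1:
        with ThreadPoolExecutor(max_workers=options.threads) as pool:
            results = list(pool.map(run_gene, range(m)))
    else:
        results = [run_gene(j) for j in range(m)]
    for j, summ, acc in results:
        postmean[j] = summ.postmean
        lo[j] = summ.hpd_lower
        hi[j] = summ.hpd_upper
        se[j] = summ.se
        nexcl[j] = summ.n_excluded
        accept[j] = acc

    flagged = zero_genes | ~converged | (nexcl.sum(axis=1) > 0.01 * options.ns)

    # two-sided Gaussian p-values from the unshrunk estimates
    with np.errstate(divide="ignore", invalid="ignore"):
        z_raw = np.where(se > 0, postmean / se, np.inf * np.sign(postmean))
    z_raw = np.where((se == 0) & (postmean == 0), 0.0, z_raw)
    pvalue = 2.0 * ndtr(-np.abs(z_raw))

    shrunk_lfc = postmean.copy()
    shrunk_se = se.copy()
    lfsr = np.full((m, K), np.nan)
    svalue = np.full((m, K), np.nan)
    if options.shrink:
        for k in range(K):
            _, est = adaptive_shrink(postmean[:, k], se[:, k])
            shrunk_lfc[:, k] = est.posterior_mean
            shrunk_se[:, k] = est.posterior_sd
            lfsr[:, k] = est.lfsr
            svalue[:, k] = est.svalue
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(shrunk_se > 0, shrunk_lfc / shrunk_se, np.nan)

    return GoMDEResult(
        feature_ids=feature_ids,
        postmean_lfc=postmean,
        hpd_lower=lo,
        hpd_upper=hi,
        se=se,
        shrunk_lfc=shrunk_lfc,
        shrunk_se=shrunk_se,
        zscore=zscore,
        lfsr=lfsr,
        svalue=svalue,
        pvalue=pvalue,
        p0=p0_raw,
        f_map=P_map,
        options=replace(options),
        flagged=flagged,
    )
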