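"""Synthetic single-cell count data with known topic structure and DE truth.

The generator emulates UMI counts from scRNA-seq experiments.  Per cell,
a total-count scale s_i = 10^u, u ~ N(0, sd 1/5), and membership
proportions drawn by first choosing the number of nonzero topics K' with
probability proportional to 2^(-K') over {1..K}, picking the K' topics
uniformly without replacement and drawing their proportions from a
Dirichlet (a single selected topic gets proportion 1).  Per gene, a base
rate 2^v with v ~ N(-4, sd 2); with probability 0.5 the gene is
differentially expressed, in which case one uniformly chosen topic's rate
becomes 2^(v + e), e ~ N(0, sd 1).  Counts are Poisson with rates
s_i * sum_k l_ik f_jk.

Three preset collections are provided: "k2-hard" (K=2, alpha=(0.01, 0.01),
n=200: essentially discrete groups), "k2-soft" (K=2, alpha=(1, 1), n=200)
and "k6" (K=6, alpha=1, n=1000).  All presets use m=10,000 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topic_model import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "PRESETS",
    "sim_sizes",
    "sim_memberships",
    "sim_rates",
    "sim_counts",
    "sim_dataset",
]

# RNG stream tags: derived seeds keep s and L unchanged when m changes
_TAG_SIZES, _TAG_MEMBERSHIPS, _TAG_RATES, _TAG_COUNTS = 1, 2, 3, 4


@dataclass
class SimConfig:
    n: int = 200
    m: int = 10_000
    K: int = 2
    dirichlet_alpha: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0])
    )
    seed: int = 1
    de_prob: float = 0.5

    def __post_init__(self):
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if self.dirichlet_alpha.size != self.K:
            raise ValueError("dirichlet_alpha must have length K")
        if np.any(self.dirichlet_alpha <= 0):
            raise ValueError("dirichlet_alpha must be positive")


PRESETS = {
    "k2-hard": dict(n=200, m=10_000, K=2, dirichlet_alpha=(0.01, 0.01)),
    "k2-soft": dict(n=200, m=10_000, K=2, dirichlet_alpha=(1.0, 1.0)),
    "k6": dict(n=1000, m=10_000, K=6, dirichlet_alpha=(1.0,) * 6),
}


def preset_config(name: str, seed: int = 1, m: int | None = None) -> SimConfig:
    """Build the configuration for a named preset collection.

    ``m`` may be overridden to scale a collection down; all other settings
    are the preset's own.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    if m is not None:
        kw["m"] = m
    kw["dirichlet_alpha"] = np.asarray(kw["dirichlet_alpha"])
    return SimConfig(seed=seed, **kw)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    counts: CountMatrix
    L_true: np.ndarray
    s_true: np.ndarray
    F_true: np.ndarray
    de_mask: np.ndarray  # m x K booleans, one true column per DE gene
    de_sign: np.ndarray  # m vector: sign of the perturbation (0 if none)
    de_effect: np.ndarray  # m vector: the log2 effect e (0 if none)
    config: SimConfig | None = None


def sim_sizes(n: int, seed: int = 1) -> np.ndarray:
    """Cell size factors s_i = 10^u with u ~ N(0, sd 1/5)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, _TAG_SIZES])
    u = rng.normal(0.0, 0.2, size=n)
    return 10.0**u


def _kprime_probs(K: int) -> np.ndarray:
    w = 2.0 ** -np.arange(1, K + 1)
    return w / w.sum()


def sim_memberships(n: int, K: int, alpha, seed: int = 1) -> np.ndarray:
    """Membership proportions with a wide range of mixed memberships.

    The K' probabilities 2^(-K') are normalized over {1..K} so they form a
    distribution.  When K' = 1 the selected topic's proportion is set to 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size != K:
        raise ValueError("alpha must have length K")
    rng = np.random.default_rng([seed, _TAG_MEMBERSHIPS])
    probs = _kprime_probs(K)
    L = np.zeros((n, K))
    kprime = rng.choice(np.arange(1, K + 1), size=n, p=probs)
    for i in range(n):
        kp = kprime[i]
        topics = rng.choice(K, size=kp, replace=False)
        if kp == 1:
            L[i, topics[0]] = 1.0
        else:
            # gamma-normalization form of the Dirichlet; with very small
            # shapes all draws can underflow to 0, in which case the mass
            # collapses onto one selected topic chosen by the shape weights
            g = rng.gamma(alpha[topics], 1.0)
            tot = g.sum()
            if tot <= 0:
                w = alpha[topics] / alpha[topics].sum()
                L[i, topics[rng.choice(kp, p=w)]] = 1.0
            else:
                L[i, topics] = g / tot
    return L


def sim_rates(m: int, K: int, seed: int = 1, de_prob: float = 0.5):
    """Per-gene expression rates, DE mask and perturbation signs/effects.

    Returns (F_true (m x K), de_mask (m x K) bool, de_sign (m,), de_effect (m,)).
    """
    rng = np.random.default_rng([seed, _TAG_RATES])
    v = rng.normal(-4.0, 2.0, size=m)
    F = np.tile((2.0**v)[:, None], (1, K))
    de_mask = np.zeros((m, K), dtype=bool)
    de_sign = np.zeros(m)
    de_effect = np.zeros(m)
    is_de = rng.random(m) < de_prob
    topics = rng.integers(0, K, size=m)
    e = rng.normal(0.0, 1.0, size=m)
    for j in np.nonzero(is_de)[0]:
        F[j, topics[j]] = 2.0 ** (v[j] + e[j])
        de_mask[j, topics[j]] = True
        de_sign[j] = np.sign(e[j])
        de_effect[j] = e[j]
    return F, de_mask, de_sign, de_effect


def sim_counts(L_true, F_true, s, seed: int = 1) -> CountMatrix:
    """Poisson counts x_ij ~ Poisson(s_i * sum_k l_ik f_jk), stored sparse."""
    L_true = np.asarray(L_true, dtype=float)
    F_true = np.asarray(F_true, dtype=float)
    s = np.asarray(s, dtype=float)
    if L_true.shape[1] != F_true.shape[1] or L_true.shape[0] != s.size:
        raise ValueError("shapes of L, F and s do not agree")
    rng = np.random.default_rng([seed, _TAG_COUNTS])
    lam = s[:, None] * (L_true @ F_true.T)
    X = rng.poisson(lam)
    return CountMatrix.from_array(X)


def sim_dataset(config: SimConfig) -> SimTruth:
    """Chain sizes -> memberships -> rates -> counts and record the truth."""
    s = sim_sizes(config.n, config.seed)
    L = sim_memberships(
        config.n, config.K, config.dirichlet_alpha, config.seed
    )
    F, de_mask, de_sign, de_effect = sim_rates(
        config.m, config.K, config.seed, de_prob=config.de_prob
    )
    counts = sim_counts(L, F, s, config.seed)
    return SimTruth(
        counts=counts,
        L_true=L,
        s_true=s,
        F_true=F,
        de_mask=de_mask,
        de_sign=de_sign,
        de_effect=de_effect,
        config=config,
    )
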