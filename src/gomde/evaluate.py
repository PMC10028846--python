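"""Benchmark harness: K-L divergence baseline, confusion counts and
power/FDR/FPR curves for differential-expression rankings.

Definitions: power = TP / (TP + FN), FDR = FP / (TP + FP) (0 when no
discoveries), FPR = FP / (TN + FP).  Since the K-L divergence ranking is
unsigned, evaluations may be restricted to the positive-direction true
effects; truly-null pairs are kept and negative-direction true effects are
removed from the candidate set entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gom_de import GoMDEResult
from .simulate import SimTruth

__all__ = [
    "EvalScores",
    "PerfCurve",
    "kl_scores",
    "restrict_positive",
    "perf_curve",
    "fdr_at_power",
    "seed_concordance",
]

_KL_FLOOR = 1e-15


@dataclass
class EvalScores:
    """Per gene x topic significance scores and their ordering direction."""

    values: np.ndarray  # m x K
    kind: str  # "lfsr", "svalue", "pvalue" or "kl"
    small_is_significant: bool
    flagged: np.ndarray | None = None  # rate floor applied (K-L only)


@dataclass
class PerfCurve:
    thresholds: np.ndarray
    TP: np.ndarray
    FP: np.ndarray
    TN: np.ndarray
    FN: np.ndarray
    power: np.ndarray
    FDR: np.ndarray
    FPR: np.ndarray


def kl_scores(F_hat, L=None) -> EvalScores:
    """Distinctiveness ranking from per-gene Poisson K-L divergences.

    score_jk = min over l != k of f_jk log(f_jk / f_jl) + f_jl - f_jk,
    floored at 0.  Large scores flag genes with large differences in
    expression and high overall expression; zero rates in the comparison
    topic are floored at 1e-15 and flagged.
    """
    F = np.asarray(F_hat, dtype=float)
    if np.any(F < 0):
        raise ValueError("rates must be non-negative")
    m, K = F.shape
    scores = np.full((m, K), np.inf)
    flagged = np.zeros((m, K), dtype=bool)
    for k in range(K):
        fk = F[:, k]
        for l in range(K):
            if l == k:
                continue
            fl = F[:, l].copy()
            floor_needed = (fl == 0) & (fk > 0)
            flagged[:, k] |= floor_needed
            fl = np.maximum(fl, _KL_FLOOR)
            with np.errstate(divide="ignore", invalid="ignore"):
                div = np.where(
                    fk > 0, fk * np.log(fk / fl) + fl - fk, fl
                )
            scores[:, k] = np.minimum(scores[:, k], np.maximum(div, 0.0))
    return EvalScores(
        values=scores, kind="kl", small_is_significant=False, flagged=flagged
    )


def scores_from_result(result: GoMDEResult, stat: str) -> EvalScores:
    """Extract a significance table from a GoM DE result."""
    if stat == "lfsr":
        vals = result.lfsr
    elif stat == "svalue":
        vals = result.svalue
    elif stat == "pvalue":
        vals = result.pvalue
    elif stat == "kl":
        return kl_scores(result.f_map)
    else:
        raise ValueError(f"unknown statistic {stat!r}")
    return EvalScores(values=vals, kind=stat, small_is_significant=True)


def restrict_positive(scores: EvalScores, truth: SimTruth, estimated_lfc=None):
    """Candidate (gene, topic) pairs for a signed evaluation.

    Keeps pairs whose true perturbation is positive (the positives) plus
    all truly-null pairs; pairs carrying a negative-direction true effect
    are removed from the candidate set entirely.  When ``estimated_lfc``
    (an m x K table of estimated log-fold changes) is supplied, tests whose
    estimated difference is non-positive are also dropped — with symmetric
    effects this removes roughly half of all possible tests, which is how
    an unsigned ranking such as the K-L score can be compared on equal
    footing.  Returns (values, is_true, keep_mask), the first two
    flattened over the kept pairs.
    """
    vals = scores.values
    if vals.shape != truth.de_mask.shape:
        raise ValueError("scores and truth have different shapes")
    positive = truth.de_mask & (truth.de_sign[:, None] > 0)
    negative = truth.de_mask & (truth.de_sign[:, None] < 0)
    keep = ~negative
    if estimated_lfc is not None:
        estimated_lfc = np.asarray(estimated_lfc, dtype=float)
        if estimated_lfc.shape != vals.shape:
            raise ValueError("estimated_lfc and scores have different shapes")
        keep &= estimated_lfc > 0
    return vals[keep], positive[keep], keep


def perf_curve(values, is_true, small_is_significant=True) -> PerfCurve:
    """Sweep all unique score values as thresholds and classify.

    ``values`` and ``is_true`` are aligned 1-d arrays over the candidate
    set.  NaN scores are treated as never significant.
    """
    values = np.asarray(values, dtype=float).ravel()
    is_true = np.asarray(is_true, dtype=bool).ravel()
    if values.shape != is_true.shape:
        raise ValueError("values and truth labels must align")
    if not is_true.any():
        raise ValueError("no true positives in the candidate set")
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("all scores are NaN")
    v = values[finite]
    t = is_true[finite]
    n_nan_true = int(is_true[~finite].sum())

    # order from most to least significant, then accumulate
    order = np.argsort(v, kind="stable")
    if not small_is_significant:
        order = order[::-1]
    v_sorted = v[order]
    t_sorted = t[order]
    # group ties: thresholds are the unique score values
    boundaries = np.nonzero(np.diff(v_sorted))[0]
    idx = np.concatenate([boundaries, [v.size - 1]])
    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    TP = cum_tp[idx]
    FP = cum_fp[idx]
    P = int(t.sum()) + n_nan_true
    N = int((~is_true).sum())
    FN = P - TP
    TN = N - FP
    thresholds = v_sorted[idx]
    power = TP / P
    with np.errstate(invalid="ignore", divide="ignore"):
        FDR = np.where(TP + FP > 0, FP / np.maximum(TP + FP, 1), 0.0)
        FPR = FP / max(N, 1)
    return PerfCurve(
        thresholds=thresholds,
        TP=TP,
        FP=FP,
        TN=TN,
        FN=FN,
        power=power,
        FDR=FDR,
        FPR=FPR,
    )


def fdr_at_power(curve: PerfCurve, power_level: float) -> float:
    """FDR at the tightest threshold whose power reaches ``power_level``."""
    idx = np.nonzero(curve.power >= power_level)[0]
    if idx.size == 0:
        return float("nan")
    return float(curve.FDR[idx[0]])


def seed_concordance(resultA: GoMDEResult, resultB: GoMDEResult) -> dict:
    """Consistency of two independent MCMC runs on the same data.

    Pearson correlations of post-shrinkage posterior means and z-scores,
    plus maximum absolute differences; the field's standard check that the
    chain length ns was large enough.
    """
    if resultA.postmean_lfc.shape != resultB.postmean_lfc.shape:
        raise ValueError("results have different shapes")

    def _corr(a, b):
        a = a.ravel()
        b = b.ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            return float("nan")
        return float(np.corrcoef(a[ok], b[ok])[0, 1])

    def _maxdiff(a, b):
        d = np.abs(a - b).ravel()
        d = d[np.isfinite(d)]
        return float(d.max()) if d.size else float("nan")

    return {
        "postmean_corr": _corr(resultA.shrunk_lfc, resultB.shrunk_lfc),
        "zscore_corr": _corr(resultA.zscore, resultB.zscore),
        "postmean_maxdiff": _maxdiff(resultA.shrunk_lfc, resultB.shrunk_lfc),
        "zscore_maxdiff": _maxdiff(resultA.zscore, resultB.zscore),
        "raw_postmean_corr": _corr(resultA.postmean_lfc, resultB.postmean_lfc),
    }
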