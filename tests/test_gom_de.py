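"""The GoM DE engine: MAP rates, LFC statistics, MCMC and summaries."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln, psi

from gomde import (
    GoMDEOptions,
    de_analysis,
    fit_gom_map,
    fit_null,
    hpd_interval,
    le_lfc,
    mcmc_gene,
    null_lfc,
    pairwise_lfc,
    summarize_posterior,
)
from gomde.gom_de import _lfc_samples, _mh_kernel_py, acceptance_probability


class TestFitNull:
    @pytest.mark.parametrize(
        "x, s, eps, expected",
        [
            ((1, 2, 3), (10, 10, 10), 0.0, 0.2),
            ((0, 0, 0), (5, 5, 5), 0.0, 0.0),
            ((5,), (10,), 0.1, 5.1 / 11),
        ],
    )
    def test_closed_forms(self, x, s, eps, expected):
        assert fit_null(np.array(x, float), np.array(s, float), eps) == pytest.approx(
            expected
        )

    def test_augmented_form_is_the_one_parameter_map(self):
        # grid-search the log-posterior of the K=1 Poisson-gamma model
        x, s, eps = np.array([5.0]), np.array([10.0]), 0.1
        grid = np.linspace(1e-4, 2.0, 200_001)
        logpost = (x.sum() + eps) * np.log(grid) - (s.sum() + 1.0) * grid
        assert fit_null(x, s, eps) == pytest.approx(grid[np.argmax(logpost)], abs=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fit_null(np.array([-1.0]), np.array([1.0]))


def _neg_log_posterior(logp, x, L, s, eps):
    """Independent oracle: -(Poisson loglik + Gamma(1+eps, 1) log prior)."""
    p = np.exp(logp)
    theta = L @ p
    lam = s * theta
    ll = np.sum(np.where(x > 0, x * np.log(lam), 0.0)) - lam.sum()
    ll += np.sum(eps * np.log(p) - p)  # Gamma(1+eps,1) log density, up to const
    return -ll


class TestFitGomMap:
    def test_hard_groups_closed_form(self, hard_two_group):
        X, L, s = hard_two_group
        eps = 0.1
        for j in range(X.shape[1]):
            rates = fit_gom_map(X[:, j].astype(float), L, s, pseudocount=eps)
            for k in range(2):
                grp = L[:, k] == 1
                expected = (X[grp, j].sum() + eps) / (s[grp].sum() + 1.0)
                assert rates.p[k] == pytest.approx(expected, rel=1e-8)

    def test_K1_reduces_to_null(self):
        x = np.array([4.0, 1.0, 0.0])
        s = np.array([5.0, 10.0, 2.0])
        rates = fit_gom_map(x, np.ones((3, 1)), s, pseudocount=0.1)
        assert rates.p[0] == pytest.approx(fit_null(x, s, 0.1), rel=1e-10)

    def test_duplicate_topics_get_symmetric_solution(self):
        rng = np.random.default_rng(5)
        Lhalf = rng.dirichlet((1.0, 1.0), size=6)
        L = np.column_stack([Lhalf[:, 0] / 2, Lhalf[:, 0] / 2, Lhalf[:, 1]])
        x = rng.poisson(3.0, size=6).astype(float)
        s = np.full(6, 10.0)
        rates = fit_gom_map(x, L, s, pseudocount=0.1)
        assert rates.p[0] == pytest.approx(rates.p[1], rel=1e-6)

    def test_matches_numerical_map_on_random_instances(self):
        # the augmentation identity: MAP via pseudocount-augmented MLE equals
        # an independent K-dimensional numerical optimization
        rng = np.random.default_rng(11)
        for _ in range(20):
            K = rng.integers(2, 4)
            L = rng.dirichlet(np.ones(K), size=5)
            s = rng.uniform(1.0, 20.0, size=5)
            x = rng.poisson(2.0, size=5).astype(float)
            eps = 0.1
            rates = fit_gom_map(x, L, s, pseudocount=eps)
            opt = minimize(
                _neg_log_posterior,
                np.zeros(K),
                args=(x, L, s, eps),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            assert np.allclose(rates.p, np.exp(opt.x), atol=1e-6, rtol=1e-5)

    def test_bad_membership_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fit_gom_map(np.array([1.0]), np.array([[0.4, 0.4]]), np.array([1.0]))


class TestLFCStatistics:
    def test_pairwise_values(self):
        p = np.array([0.01, 0.0001])
        assert pairwise_lfc(p, 0, 1) == pytest.approx(math.log2(100), abs=0.01)
        assert pairwise_lfc(p, 1, 0) == pytest.approx(-math.log2(100), abs=0.01)
        assert pairwise_lfc(np.array([0.3, 0.3]), 0, 1) == 0.0
        assert pairwise_lfc(np.array([0.0, 0.0]), 0, 1) == 0.0
        assert pairwise_lfc(np.array([0.1, 0.0]), 0, 1) == np.inf

    def test_least_extreme_toy_example(self):
        # the K=10 walkthrough: high expression in one topic is distinctive,
        # high expression shared with a second topic is not
        p1 = np.array([0.01] + [0.0001] * 9)
        assert le_lfc(p1, 0) == pytest.approx(math.log2(100), abs=1e-12)
        p2 = np.array([0.01, 0.01] + [0.0001] * 8)
        assert le_lfc(p2, 0) == 0.0

    def test_least_extreme_minimum_absolute(self):
        assert le_lfc(np.array([4.0, 1.0, 2.0]), 0) == pytest.approx(1.0)

    def test_least_extreme_requires_two_topics(self):
        with pytest.raises(ValueError, match="K = 1"):
            le_lfc(np.array([1.0]), 0)

    def test_null_lfc(self):
        assert null_lfc(np.array([0.2]), 0, p0=0.2) == 0.0
        assert null_lfc(np.array([0.4]), 0, p0=0.2) == pytest.approx(1.0)
        assert null_lfc(np.array([0.4]), 0, p0=0.0) == np.inf

    def test_null_lfc_from_dataset(self, hard_two_group):
        X, L, s = hard_two_group
        j = 0
        p0 = fit_null(X[:, j].astype(float), s)
        rates = fit_gom_map(X[:, j].astype(float), L, s, pseudocount=0.0)
        expected = math.log2(rates.p[1] / (X[:, j].sum() / s.sum()))
        assert null_lfc(rates.p, 1, p0=p0) == pytest.approx(expected)


class TestHPDInterval:
    def test_uniform_spacing_earliest_window(self):
        a, b = hpd_interval(np.arange(1, 101, dtype=float), 0.68)
        assert (a, b) == (1.0, 68.0)

    def test_point_mass_dominates(self):
        samples = np.concatenate([np.zeros(90), np.full(10, 10.0)])
        assert hpd_interval(samples, 0.68) == (0.0, 0.0)

    def test_gaussian_68_interval(self):
        x = np.random.default_rng(3).normal(size=10_000)
        a, b = hpd_interval(x, 0.68)
        assert a == pytest.approx(-1.0, abs=0.05)
        assert b == pytest.approx(1.0, abs=0.05)

    def test_invalid_level(self):
        with pytest.raises(ValueError, match="level"):
            hpd_interval(np.arange(10.0), 1.2)


class TestMCMC:
    def test_degenerate_proposal_keeps_initial_state(self, hard_two_group):
        X, L, s = hard_two_group
        opts = GoMDEOptions(ns=500, proposal_sd=1e-12, seed=0)
        g0 = np.array([-2.0, -1.0])
        chain = mcmc_gene(X[:, 0].astype(float), L, s, g0, opts)
        assert np.allclose(chain.g, g0, atol=1e-10)

    def test_K1_conjugate_stationary_distribution(self):
        # with one topic the target is Gamma(sum x + eps + 1, sum s + 1)
        rng = np.random.default_rng(21)
        x = np.array([3.0, 7.0, 1.0])
        s = np.array([10.0, 12.0, 8.0])
        eps = 0.1
        opts = GoMDEOptions(ns=100_000, pseudocount=eps, seed=0)
        chain = mcmc_gene(x, np.ones((3, 1)), s, np.array([-1.0]), opts,
                          rng=np.random.default_rng(4))
        alpha = x.sum() + eps + 1.0
        beta = s.sum() + 1.0
        mean_g = psi(alpha) - math.log(beta)
        mc_se = chain.g.std() / math.sqrt(opts.ns / 20)  # conservative ESS
        assert abs(chain.g.mean() - mean_g) < 3 * mc_se + 1e-3
        p = np.exp(chain.g[:, 0])
        assert p.mean() == pytest.approx(alpha / beta, rel=0.02)

    def test_single_step_acceptance_matches_direct_evaluation(self):
        # oracle: evaluate the Metropolis ratio from raw Poisson pmfs
        x = np.array([2.0, 0.0, 5.0])
        s = np.array([4.0, 6.0, 3.0])
        L = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
        eps = 0.1
        g_cur = np.array([-1.2, -0.4])
        g_prop = -0.9

        def direct(gk_new):
            def logpmf(p):
                x_aug = np.concatenate([x, [eps, eps]])
                L_aug = np.vstack([L, np.eye(2)])
                s_aug = np.concatenate([s, [1.0, 1.0]])
                lam = s_aug * (L_aug @ p)
                return float(
                    np.sum(x_aug * np.log(lam) - lam - gammaln(x_aug + 1))
                )

            p_cur = np.exp(g_cur)
            p_new = p_cur.copy()
            p_new[0] = math.exp(gk_new)
            ratio = math.exp(
                logpmf(p_new) - logpmf(p_cur)
            ) * (p_new[0] / p_cur[0])
            return min(1.0, ratio)

        got = acceptance_probability(x, L, s, g_cur, 0, g_prop, eps=eps)
        assert got == pytest.approx(direct(g_prop), rel=1e-12)

    def test_compiled_and_python_kernels_agree(self, hard_two_group):
        X, L, s = hard_two_group
        x = X[:, 0].astype(float)
        opts = GoMDEOptions(ns=2000, seed=0)
        g0 = np.log(np.array([0.05, 0.2]))
        chain_fast = mcmc_gene(x, L, s, g0, opts, rng=np.random.default_rng(5))

        # rebuild the same inputs and drive the pure-Python kernel
        import gomde.gom_de as mod

        saved = mod._mh_kernel
        mod._mh_kernel = _mh_kernel_py
        try:
            chain_py = mcmc_gene(x, L, s, g0, opts, rng=np.random.default_rng(5))
        finally:
            mod._mh_kernel = saved
        assert np.array_equal(chain_fast.g, chain_py.g)

    def test_nonfinite_initial_state_rejected(self, hard_two_group):
        X, L, s = hard_two_group
        with pytest.raises(ValueError, match="finite"):
            mcmc_gene(X[:, 0].astype(float), L, s, np.array([-np.inf, 0.0]),
                      GoMDEOptions(ns=10))


class TestSummarizePosterior:
    def _chain(self, G):
        from gomde import MCMCChain

        return MCMCChain(g=np.asarray(G, float), accept_rate=1.0)

    def test_constant_chain_degenerates(self):
        G = np.tile(np.log([0.2, 0.05]), (50, 1))
        summ = summarize_posterior(self._chain(G), GoMDEOptions(ns=50))
        stat = le_lfc(np.array([0.2, 0.05]), 0)
        assert summ.postmean[0] == pytest.approx(stat)
        assert summ.hpd_lower[0] == pytest.approx(stat)
        assert summ.hpd_upper[0] == pytest.approx(stat)
        assert summ.se[0] == 0.0

    def test_asymmetric_se_rule(self):
        # positive mean: se = mean - lower; negative mean: se = upper - mean
        rng = np.random.default_rng(6)
        G = np.column_stack(
            [rng.normal(2.0, 0.5, 5000) * math.log(2), np.zeros(5000)]
        )
        opts = GoMDEOptions(ns=5000, lfc_stat="pairwise", ref_topic=1)
        summ = summarize_posterior(self._chain(G), opts)
        assert summ.postmean[0] > 0
        assert summ.se[0] == pytest.approx(summ.postmean[0] - summ.hpd_lower[0])
        summ_neg = summarize_posterior(self._chain(-G), opts)
        assert summ_neg.postmean[0] < 0
        assert summ_neg.se[0] == pytest.approx(
            summ_neg.hpd_upper[0] - summ_neg.postmean[0]
        )

    def test_statistic_is_averaged_per_sample(self):
        # with K >= 3 the least extreme LFC is a nonlinear function of the
        # log rates (the comparison topic switches sample by sample), so the
        # mean of the per-sample statistic differs from the statistic at the
        # posterior-mean rates; the former is what must be returned
        rng = np.random.default_rng(8)
        n_s = 4000
        G = np.column_stack(
            [rng.normal(0.0, 1.0, n_s), np.full(n_s, -0.3), np.full(n_s, 0.3)]
        )
        opts = GoMDEOptions(ns=n_s)
        per_sample = _lfc_samples(G, 0, opts).mean()
        at_mean = le_lfc(np.exp(G.mean(axis=0)), 0)
        summ = summarize_posterior(self._chain(G), opts)
        assert summ.postmean[0] == pytest.approx(per_sample, rel=1e-12)
        assert abs(per_sample - at_mean) > 0.05


class TestDeAnalysis:
    def test_fig2_gene1_recovered_from_counts(self):
        # hard-membership K=10 dataset built from the toy example's gene 1
        rng = np.random.default_rng(123)
        K, cells_per_topic, s_i = 10, 100, 10_000
        n = K * cells_per_topic
        L = np.zeros((n, K))
        for k in range(K):
            L[k * cells_per_topic : (k + 1) * cells_per_topic, k] = 1.0
        p_true = np.array([0.01] + [0.0001] * 9)
        lam = s_i * (L @ p_true)
        X = rng.poisson(lam)[:, None]
        res = de_analysis(
            X, L, GoMDEOptions(ns=3000, seed=9, shrink=False),
            size_factors=float(s_i),
        )
        assert res.postmean_lfc[0, 0] == pytest.approx(math.log2(100), abs=0.3)

    def test_thread_count_does_not_change_results(self, hard_two_group):
        X, L, s = hard_two_group
        opts1 = GoMDEOptions(ns=1000, seed=4, threads=1, shrink=False)
        opts2 = GoMDEOptions(ns=1000, seed=4, threads=3, shrink=False)
        a = de_analysis(X, L, opts1)
        b = de_analysis(X, L, opts2)
        assert np.array_equal(a.postmean_lfc, b.postmean_lfc)
        assert np.array_equal(a.se, b.se)

    def test_hard_membership_reduction_to_two_group_poisson(self, hard_two_group):
        # binary memberships, K=2: the MAP-based LFC equals the pseudocounted
        # two-group Poisson rate ratio
        X, L, s = hard_two_group
        eps = 0.1
        res = de_analysis(
            X, L,
            GoMDEOptions(ns=10, seed=0, shrink=False, pseudocount=eps),
            size_factors=s,
        )
        for j in range(X.shape[1]):
            grp0 = L[:, 0] == 1
            p0 = (X[grp0, j].sum() + eps) / (s[grp0].sum() + 1.0)
            p1 = (X[~grp0, j].sum() + eps) / (s[~grp0].sum() + 1.0)
            expected = math.log2(p1 / p0)
            assert np.log2(res.f_map[j, 1] / res.f_map[j, 0]) == pytest.approx(
                expected, abs=1e-6
            )

    def test_zero_count_gene_is_flagged_not_fatal(self):
        rng = np.random.default_rng(2)
        L = rng.dirichlet((1.0, 1.0), size=10)
        X = rng.poisson(2.0, size=(10, 3))
        X[:, 1] = 0
        res = de_analysis(X, L, GoMDEOptions(ns=200, seed=1, shrink=False))
        assert res.flagged[1]
        assert np.all(np.isfinite(res.postmean_lfc[0]))
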