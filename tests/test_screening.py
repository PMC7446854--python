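"""Count-model likelihoods, Laplace accuracy, LRT and q-values."""

from __future__ import annotations

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, kstest, poisson

from mbpredict import _glmm_kernels as K
from mbpredict.io_filters import OTUTable, SampleCovariates
from mbpredict.screening import (
    REGIME_DROPPED,
    compute_qvalues,
    fit_count_glmm,
    fit_hurdle,
    lrt,
    nb_logpmf,
    screen_all,
    select_otus,
    tpnb_dispatch,
)


def _loglik_vec(family, z, eta, theta, gz):
    """Independent per-observation log-likelihoods (plain numpy)."""
    from scipy.special import gammaln

    if family == K.BERNOULLI:
        return z * eta - np.logaddexp(0.0, eta)
    mu = np.exp(eta)
    lnb = (gammaln(z + theta) - gammaln(theta) - gammaln(z + 1)
           + theta * (np.log(theta) - np.log(theta + mu))
           + z * (eta - np.log(theta + mu)))
    if family == K.NB:
        return lnb
    lp0 = theta * (np.log(theta) - np.log(theta + mu))
    if family == K.TRUNC_NB:
        return lnb - np.log1p(-np.exp(lp0))
    phi = 1.0 / (1.0 + np.exp(-gz))
    out = np.where(z > 0, np.log1p(-phi) + lnb,
                   np.log(phi + (1 - phi) * np.exp(lp0)))
    return out


def agh_marginal_loglik(family, z, eta, gz, theta, sigma2, groups, nodes=64):
    """Adaptive Gauss–Hermite oracle for the marginal log-likelihood."""
    x, w = hermgauss(nodes)
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        zz, ee, gg = z[m], eta[m], gz[m]

        def negh(b):
            return -(np.sum(_loglik_vec(family, zz, ee + b, theta, gg)) - b * b / (2 * sigma2))

        mode = minimize_scalar(negh, bounds=(-10.0, 10.0), method="bounded",
                               options={"xatol": 1e-10}).x
        hpp = (-negh(mode + 1e-4) - negh(mode - 1e-4) + 2 * negh(mode)) / 1e-8
        scale = 1.0 / np.sqrt(max(-hpp, 1e-8))
        bs = mode + np.sqrt(2.0) * scale * x
        hv = np.array([-negh(b) for b in bs])
        m0 = hv.max()
        integral = np.sqrt(2.0) * scale * np.sum(w * np.exp(x**2 + hv - m0))
        total += m0 + np.log(integral) - 0.5 * np.log(2 * np.pi * sigma2)
    return total


class TestNbLogpmf:
    def test_zero_count_closed_form(self):
        mu, theta = 3.7, 1.3
        assert nb_logpmf(0, mu, theta) == pytest.approx(theta * (np.log(theta) - np.log(theta + mu)))

    def test_poisson_limit(self):
        # the NB->Poisson error is O((z-mu)^2/theta); over the probable
        # region (>99.99% of the mass at mu=4.2) it is below 1e-4 at theta=1e6
        z = np.arange(0, 16)
        mu = 4.2
        diff = np.abs(nb_logpmf(z, mu, 1e6) - poisson.logpmf(z, mu))
        assert diff.max() < 1e-4

    def test_normalizes(self):
        z = np.arange(0, 500)
        total = np.exp(nb_logpmf(z, 3.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)


class TestDispatch:
    @pytest.mark.parametrize(
        "zp,regime",
        [(0.0, "nb"), (0.05, "nb"), (0.10, "nb"), (0.1001, "hurdle"), (0.5, "hurdle"),
         (0.80, "hurdle"), (0.8001, "logistic"), (0.85, "logistic"), (0.8999, "logistic"),
         (0.90, "dropped"), (0.95, "dropped"), (1.0, "dropped")],
    )
    def test_boundaries(self, zp, regime):
        assert tpnb_dispatch(zp) == regime

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tpnb_dispatch(1.5)


class TestLrt:
    def test_equal_likelihoods_give_p_one(self):
        t, p = lrt(-10.0, -10.0, 1)
        assert t == 0.0 and p == 1.0

    @pytest.mark.parametrize("stat,df", [(3.8415, 1), (5.9915, 2)])
    def test_chi_square_tail_oracle(self, stat, df):
        _, p = lrt(0.0, stat / 2.0, df)
        assert p == pytest.approx(chi2.sf(stat, df))
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_negative_statistic_clipped(self):
        t, p = lrt(-9.0, -9.5, 1)
        assert t == 0.0 and p == 1.0

    def test_nonconvergence_forces_p_one(self):
        _, p = lrt(-20.0, -5.0, 1, both_converged=False)
        assert p == 1.0

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            lrt(-1.0, 0.0, 0)


class TestGlmmFits:
    def test_constant_counts_intercept_only(self):
        z = np.array([3, 3, 3, 3])
        X = np.ones((4, 1))
        fit = fit_count_glmm(z, X, np.zeros(4), None, "nb")
        assert fit.beta[0] == pytest.approx(np.log(3), abs=1e-3)

    def test_single_group_collapses_to_glm(self):
        rng = np.random.default_rng(0)
        n = 60
        off = np.log(rng.integers(500, 2000, n).astype(float))
        z = rng.negative_binomial(1.5, 1.5 / (1.5 + np.exp(off - 5.0)))
        X = np.ones((n, 1))
        glm = fit_count_glmm(z, X, off, None, "nb")
        one_group = fit_count_glmm(z, X, off, np.zeros(n, dtype=int), "nb")
        assert one_group.loglik == pytest.approx(glm.loglik, abs=1e-6)

    @pytest.mark.parametrize(
        "family,n,theta",
        [("nb", 300, 10.0), ("truncated_nb", 300, 10.0),
         ("bernoulli", 16000, 1.0), ("zinb", 400, 10.0)],
    )
    def test_laplace_matches_adaptive_quadrature(self, family, n, theta):
        # 5-group instances sized so each group carries enough Fisher
        # information for the Laplace expansion to be in its accurate
        # regime (the NB curvature per observation is bounded by theta,
        # and a Bernoulli observation contributes at most 1/4)
        rng = np.random.default_rng(42)
        groups = np.repeat(np.arange(5), n // 5)
        gs = np.concatenate([[0], np.cumsum(np.bincount(groups))]).astype(np.int64)
        off = np.log(rng.integers(2_000, 8_000, n).astype(float))
        x = rng.normal(size=n)
        b_true = np.array([-0.8, -0.4, 0.0, 0.4, 0.8])
        eta = off - 5.0 + 0.3 * x + b_true[groups]
        z = rng.negative_binomial(theta, theta / (theta + np.exp(eta))).astype(float)
        X = np.column_stack([np.ones(n), x])
        if family == "bernoulli":
            resp, fam, offv = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.4 + 0.3 * x + b_true[groups])))).astype(float), K.BERNOULLI, np.zeros(n)
        elif family == "truncated_nb":
            resp, fam, offv = np.maximum(z, 1.0), K.TRUNC_NB, off
        elif family == "zinb":
            resp, fam, offv = np.where(rng.uniform(size=n) < 0.25, 0.0, z), K.ZINB, off
        else:
            resp, fam, offv = z, K.NB, off
        gz = np.full(n, -1.0) if family == "zinb" else np.zeros(n)
        eta_fix = offv + X @ np.array([-5.0 if family != "bernoulli" else 0.4, 0.3])
        for sigma2 in (0.05, 0.4, 1.5):
            lap = -K.marginal_nll(fam, resp, eta_fix, gz, theta, sigma2, gs, True)
            agh = agh_marginal_loglik(fam, resp, eta_fix, gz, theta, sigma2, groups)
            assert lap == pytest.approx(agh, abs=1e-3)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        n = 40
        groups = np.repeat(np.arange(4), n // 4)
        gs = np.concatenate([[0], np.cumsum(np.bincount(groups))]).astype(np.int64)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        off = np.log(rng.integers(500, 3000, n).astype(float))
        Z0 = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        z = rng.negative_binomial(1.3, 1.3 / (1.3 + np.exp(off - 5.5))).astype(float)
        z = np.where(rng.uniform(size=n) < 0.3, 0.0, z)
        cases = [
            (K.NB, z, np.zeros((n, 0)), True),
            (K.TRUNC_NB, np.maximum(z, 1.0), np.zeros((n, 0)), True),
            (K.BERNOULLI, (z > 0).astype(float), np.zeros((n, 0)), False),
            (K.ZINB, z, Z0, True),
        ]
        for fam, resp, Z0use, has_theta in cases:
            p, q = X.shape[1], Z0use.shape[1]
            npar = p + q + int(has_theta) + 1
            x0 = np.concatenate([
                [-5.0 if fam != K.BERNOULLI else 0.2], [0.1],
                rng.normal(0, 0.2, q), [0.15] * int(has_theta), [np.log(0.5)],
            ])

            def f(xv):
                beta = xv[:p]
                gam = xv[p:p + q]
                theta = float(np.exp(xv[p + q])) if has_theta else 1.0
                s2 = float(np.exp(xv[-1]))
                bc = np.zeros(len(gs) - 1)
                return K.nll_and_grad(fam, resp, X, off if fam not in (K.BERNOULLI,) else np.zeros(n),
                                      Z0use, beta, gam, theta, s2, gs, True, has_theta, bc)

            _, g = f(x0)
            for j in range(npar):
                e = np.zeros(npar)
                e[j] = 1e-6
                fd = (f(x0 + e)[0] - f(x0 - e)[0]) / 2e-6
                assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_statistic_grows_linearly_with_sample_size(self):
        # under a fixed strong signal the LRT statistic is ~ n * KL
        rng = np.random.default_rng(8)
        stats = {}
        for n in (150, 300):
            y = rng.integers(0, 2, n).astype(float)
            off = np.log(np.full(n, 1000.0))
            eta = off - 4.0 + 0.8 * y
            z = rng.negative_binomial(2.0, 2.0 / (2.0 + np.exp(eta)))
            X0 = np.ones((n, 1))
            X1 = np.column_stack([np.ones(n), y])
            f0 = fit_count_glmm(z, X0, off, None, "nb")
            f1 = fit_count_glmm(z, X1, off, None, "nb")
            stats[n] = 2 * (f1.loglik - f0.loglik)
        assert stats[300] == pytest.approx(2 * stats[150], rel=0.5)

    def test_hurdle_loglik_is_sum_of_parts(self):
        rng = np.random.default_rng(5)
        n = 80
        off = np.log(rng.integers(500, 2000, n).astype(float))
        z = rng.negative_binomial(1.0, 1.0 / (1.0 + np.exp(off - 5.0)))
        z = np.where(rng.uniform(size=n) < 0.4, 0, z)
        X = np.ones((n, 1))
        fp, fc, total, ok = fit_hurdle(z, X, off, None)
        assert total == pytest.approx(fp.loglik + fc.loglik)


class TestQValues:
    def test_worked_example(self):
        q = compute_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        assert np.allclose(q, 0.04)

    def test_single_p_is_itself(self):
        assert compute_qvalues(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_identical_ps(self):
        q = compute_qvalues(np.full(7, 0.2))
        assert np.allclose(q, 0.2)

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=300)
        q = compute_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_reference_step_up_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(5, 200))
            ours = compute_qvalues(p, method="bh")
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_storey_pi0_shrinks_qvalues(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(0, 1e-4, 30), rng.uniform(size=100)])
        q_bh = compute_qvalues(p, method="bh")
        q_st = compute_qvalues(p, method="storey", zeta=0.5)
        assert np.all(q_st <= q_bh + 1e-12)

    def test_empty_input(self):
        assert compute_qvalues(np.array([])).size == 0

    def test_select_otus_matches_brute_force(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)

        class R:
            q_value = compute_qvalues(p)

        sel = select_otus(R, 0.2)
        assert np.array_equal(sel, np.flatnonzero(R.q_value <= 0.2))
        R.q_value = np.ones(10)
        assert select_otus(R, 0.05).size == 0


def _null_table(n=120, m=200, seed=0):
    """Counts independent of the phenotype (the LRT null)."""
    rng = np.random.default_rng(seed)
    totals = rng.integers(2_000, 10_000, n)
    props = rng.dirichlet(np.full(m, 0.6), size=n)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(totals[i], props[i])
    table = OTUTable(counts, totals, tuple(f"s{i}" for i in range(n)),
                     tuple(f"t{j}" for j in range(m)))
    covs = SampleCovariates(phenotype=rng.integers(0, 2, n),
                            sample_ids=table.sample_ids)
    return table, covs


class TestScreenAll:
    def test_dropped_otu_has_p_one(self, small_dataset):
        table, covs, _ = small_dataset
        counts = table.counts.copy()
        counts[:, 0] = 0
        counts[:3, 0] = 1  # zero proportion 95%
        t2 = OTUTable(counts, table.totals, table.sample_ids, table.taxon_ids)
        scr = screen_all(t2, covs, model="tpnb", include_random=False)
        assert scr.regime[0] == REGIME_DROPPED
        assert scr.p_value[0] == 1.0

    def test_null_pvalues_are_uniform(self):
        table, covs = _null_table()
        scr = screen_all(table, covs, model="nb", include_random=False)
        testable = np.array(scr.regime) != REGIME_DROPPED
        stat = kstest(scr.p_value[testable], "uniform")
        assert stat.pvalue > 0.01

    def test_column_permutation_equivariance(self, small_dataset):
        table, covs, _ = small_dataset
        perm = np.random.default_rng(0).permutation(table.n_taxa)
        scr1 = screen_all(table, covs, model="nb", include_random=False)
        scr2 = screen_all(table.take_taxa(perm), covs, model="nb", include_random=False)
        assert np.allclose(scr1.p_value[perm], scr2.p_value, atol=1e-6)
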