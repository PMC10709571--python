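import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import kstest, nbinom

import statsmodels.api as sm

from ambigene import (DesignMatrix, SimConfig, bh_adjust, build_design,
                      estimate_dispersion, fit_nbglm, lrt_factor,
                      nb_exact_test, simulate, stack_mappers, tmm_factors)


def _offsets(stacked):
    return np.log(tmm_factors(stacked).effective_sizes)


# ---------------------------------------------------------------------------
# oracles, written from the definitions, independent of the implementation
# ---------------------------------------------------------------------------

def nb_loglik_oracle(y, mu, phi):
    """NB log-likelihood written out from the size/prob parameterization."""
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu))
                        + y * np.log(mu / (r + mu))))


def nelder_mead_fit(y, X, offset, phi, start):
    nll = lambda b: -nb_loglik_oracle(y, np.exp(offset + X @ b), phi)
    res = minimize(nll, start, method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-14, maxiter=50000,
                                maxfev=50000))
    res = minimize(nll, res.x, method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-14, maxiter=50000,
                                maxfev=50000))
    return res.x


def exact_test_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Brute-force enumeration of all partitions of the total, via nbinom/
    poisson pmfs at an arbitrary common mean (the mean cancels)."""
    from scipy.stats import poisson
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    lam = 3.7  # arbitrary per-sample mean
    if phi > 0:
        r = 1.0 / phi
        p = r / (r + lam)
        w = nbinom.pmf(a, n_a * r, p) * nbinom.pmf(s - a, n_b * r, p)
    else:
        w = poisson.pmf(a, n_a * lam) * poisson.pmf(s - a, n_b * lam)
    w = w / w.sum()
    return float(min(1.0, w[w <= w[sum_a] * (1 + 1e-10)].sum()))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

class TestBuildDesign:
    def _stacked(self, n_groups, k, n_per_group=2):
        cfg = SimConfig(n_genes=10, n_per_group=n_per_group,
                        n_groups=n_groups, k_mappers=k, seed=0)
        tables, design, _ = simulate(cfg)
        return stack_mappers(tables, design)

    def test_two_groups_three_mappers_rank_four(self):
        X = build_design(self._stacked(2, 3))
        assert X.matrix.shape == (12, 4) and X.rank == 4

    def test_three_groups_three_mappers_rank_five(self):
        X = build_design(self._stacked(3, 3))
        assert X.rank == 5

    def test_reference_level_is_lexicographically_first(self):
        s = self._stacked(2, 2)
        # group names are A/B: the reference (absorbed) level must be A
        X = build_design(s)
        assert "group[B]" in X.names and "group[A]" not in X.names
        assert X.group_levels[0] == "A"


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

class TestFitNbglm:
    def test_intercept_only_equal_offsets_gives_sample_mean(self):
        for phi in (0.0, 0.1, 1.0):
            fit = fit_nbglm(np.array([4.0, 6.0]), np.ones((2, 1)),
                            np.zeros(2), phi)
            assert np.allclose(fit.fitted_mu, [5.0, 5.0], atol=1e-6)

    def test_saturated_design_fits_exactly(self):
        y = np.array([3.0, 7.0, 11.0])
        fit = fit_nbglm(y, np.eye(3), np.zeros(3), 0.2)
        assert np.allclose(fit.fitted_mu, y, atol=1e-6)

    def test_matches_nelder_mead_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 20:
            m = 6
            X = np.column_stack([np.ones(m), rng.normal(size=m)])
            off = rng.normal(scale=0.2, size=m)
            mu = np.exp(off + X @ (rng.normal(size=2) * 0.5 + [2.0, 0.0]))
            y = rng.negative_binomial(10, 10 / (10 + mu)).astype(float)
            if y.sum() == 0:
                continue
            fit = fit_nbglm(y, X, off, 0.1)
            oracle = nelder_mead_fit(y, X, off, 0.1, fit.beta + 0.3)
            assert np.allclose(fit.beta, oracle, atol=1e-6)
            checked += 1

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(4)
        m = 8
        X = np.column_stack([np.ones(m), rng.normal(size=m)])
        off = rng.normal(scale=0.1, size=m)
        y = rng.poisson(20, m).astype(float)
        perm = rng.permutation(m)
        f1 = fit_nbglm(y, X, off, 0.2)
        f2 = fit_nbglm(y[perm], X[perm], off[perm], 0.2)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)

    def test_all_zero_gene_is_degenerate_not_crashing(self):
        fit = fit_nbglm(np.zeros(4), np.ones((4, 1)), np.zeros(4), 0.1)
        assert fit.degenerate
        assert np.all(np.abs(fit.beta) <= 50.0)

    def test_fitted_mu_consistent_with_beta_and_offset(self):
        rng = np.random.default_rng(5)
        m = 6
        X = np.column_stack([np.ones(m), rng.normal(size=m)])
        off = np.log(rng.uniform(0.5, 2.0, m))
        y = rng.poisson(30, m).astype(float)
        fit = fit_nbglm(y, X, off, 0.05)
        assert np.allclose(fit.fitted_mu, np.exp(off + X @ fit.beta),
                           rtol=1e-10)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

class TestEstimateDispersion:
    def _sim(self, phi, seed, G=600):
        cfg = SimConfig(n_genes=G, n_per_group=5, n_groups=2, k_mappers=3,
                        dispersion=phi, seed=seed)
        tables, design, _ = simulate(cfg)
        s = stack_mappers(tables, design)
        X = build_design(s)
        return s, X

    def test_poisson_data_estimates_near_lower_bound(self):
        s, X = self._sim(0.0, 21)
        disp, _ = estimate_dispersion(s, X, _offsets(s))
        assert np.median(disp) < 0.05

    def test_recovers_planted_dispersion(self):
        cfg = SimConfig(n_genes=2000, n_per_group=5, n_groups=2, k_mappers=3,
                        dispersion=0.2, seed=22)
        tables, design, _ = simulate(cfg)
        s = stack_mappers(tables, design)
        X = build_design(s)
        disp, common = estimate_dispersion(s, X, _offsets(s))
        assert 0.15 <= np.median(disp) <= 0.25
        assert 0.15 <= common <= 0.25

    def test_infinite_prior_collapses_to_common(self):
        s, X = self._sim(0.1, 23, G=200)
        disp, common = estimate_dispersion(s, X, _offsets(s),
                                           prior_df=np.inf)
        assert np.allclose(disp, common)


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

class TestLrtFactor:
    def test_reduced_equal_full_raises(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            lrt_factor(np.ones((2, 4)), X, X, np.zeros(4), 0.1)

    def test_null_simulation_type_one_error(self, null_sim):
        tables, design, _ = null_sim
        s = stack_mappers(tables, design)
        X = build_design(s)
        off = _offsets(s)
        disp, _ = estimate_dispersion(s, X, off)
        res = lrt_factor(s, X, X.drop_factor("mapper"), off, disp,
                         factor="mapper")
        rate = np.mean(res.p_value < 0.05)
        assert 0.035 <= rate <= 0.065

    def test_poisson_limit_matches_poisson_deviance_oracle(self):
        rng = np.random.default_rng(31)
        G, m = 40, 8
        X_full = np.column_stack([np.ones(m), rng.normal(size=m)])
        X_red = X_full[:, :1]
        off = np.log(rng.uniform(0.8, 1.2, m))
        y = rng.poisson(25, size=(G, m))
        res = lrt_factor(y, X_full, X_red, off, 0.0)
        for g in range(G):
            dev_full = sm.GLM(y[g], X_full, family=sm.families.Poisson(),
                              offset=off).fit().deviance
            dev_red = sm.GLM(y[g], X_red, family=sm.families.Poisson(),
                             offset=off).fit().deviance
            assert abs(res.lr_stat[g] - (dev_red - dev_full)) < 1e-8

    def test_pvalues_uniform_under_null(self, null_sim):
        tables, design, _ = null_sim
        s = stack_mappers(tables, design)
        X = build_design(s)
        off = _offsets(s)
        disp, _ = estimate_dispersion(s, X, off)
        res = lrt_factor(s, X, X.drop_factor("group"), off, disp)
        assert kstest(res.p_value, "uniform").statistic < 0.03


class TestBH:
    def test_matches_hand_computed_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.005, 0.20])
        # sorted: .005 .01 .03 .04 .20 -> *5/k: .025 .025 .05 .05 .20
        expected = np.array([0.025, 0.05, 0.05, 0.025, 0.20])
        assert np.allclose(bh_adjust(p), expected)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_identical_group_sums_give_p_one(self):
        p = nb_exact_test(np.array([[3, 4]]), np.array([[4, 3]]), 0.2)
        assert np.isclose(p[0], 1.0)

    def test_total_zero_gives_p_one(self):
        p = nb_exact_test(np.zeros((1, 3)), np.zeros((1, 2)), 0.4)
        assert p[0] == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n_a, n_b = rng.integers(2, 6, 2)
            ya = rng.poisson(6, n_a)
            yb = rng.poisson(9, n_b)
            if ya.sum() + yb.sum() > 200:
                continue
            p = nb_exact_test(ya[None, :], yb[None, :], phi)[0]
            oracle = exact_test_oracle(int(ya.sum()), int(yb.sum()),
                                       int(n_a), int(n_b), phi)
            assert abs(p - oracle) < 1e-12

    def test_equal_effective_sizes_leave_counts_unadjusted(self):
        ya = np.array([[5, 9, 2]])
        yb = np.array([[1, 0, 4]])
        p_plain = nb_exact_test(ya, yb, 0.3)
        p_eq = nb_exact_test(ya, yb, 0.3, np.ones(3), np.ones(3))
        assert np.allclose(p_plain, p_eq)

    def test_detects_large_difference(self):
        ya = np.array([[100, 120, 110]])
        yb = np.array([[10, 8, 12]])
        assert nb_exact_test(ya, yb, 0.05)[0] < 1e-4
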