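import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import countql as cq
from countql.glm import fit_levenberg, fit_one_group, nb_log_density_continuous, nb_unit_deviance


class TestUnitDeviance:
    def test_zero_at_equal_mean(self):
        assert nb_unit_deviance(5.0, 5.0, 0.1) == 0.0

    def test_zero_count_closed_form(self):
        # y=0 limit: (2/phi) log(1 + phi mu)
        got = nb_unit_deviance(0.0, 2.0, 0.5)
        assert np.isclose(got, 4 * np.log(2), rtol=1e-12)

    def test_tiny_dispersion_matches_poisson_closed_form(self):
        got = float(nb_unit_deviance(3.0, 1.0, 1e-12))
        poisson = 2 * (3 * np.log(3) - 2)
        assert np.isclose(got, poisson, rtol=1e-6)

    def test_near_equal_high_precision(self):
        # d ~ delta^2/(mu(1+phi mu)) for small delta; leading term to 1e-9
        mu, phi, delta = 100.0, 0.01, 1e-4
        d = float(nb_unit_deviance(mu + delta, mu, phi))
        lead = delta**2 / (mu * (1 + phi * mu))
        assert np.isclose(d, lead, rtol=2e-6)

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            nb_unit_deviance(1.0, 0.0, 0.1)

    def test_additivity_total_equals_sum_of_units(self, rng):
        y = rng.poisson(10, size=(5, 6)).astype(float)
        mu = np.full((5, 6), 10.0)
        d = nb_unit_deviance(y, mu, 0.1)
        fit = fit_levenberg(y, np.ones((6, 1)), np.zeros((5, 6)), 0.1)
        # residual deviance equals the sum of unit deviances at the fit
        units = nb_unit_deviance(y, fit.fitted, 0.1).sum(axis=1)
        assert np.allclose(units, fit.deviance, rtol=1e-10)
        assert (d >= 0).all()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0.0, 1e4),
        st.floats(1e-3, 1e4),
        st.floats(0.0, 10.0),
    )
    def test_nonnegative_and_zero_iff_equal(self, y, mu, phi):
        d = float(nb_unit_deviance(y, mu, phi))
        assert d >= 0.0
        if y == mu:
            assert d == 0.0

    def test_poisson_chi_square_limit(self, rng):
        # for large mu and phi=0 the unit deviance is ~ chi-square(1)
        mu = 1e4
        y = rng.poisson(mu, size=200_000).astype(float)
        d = nb_unit_deviance(y, mu, 0.0)
        assert np.isclose(d.mean(), 1.0, atol=0.02)


class TestLogDensity:
    def test_zero_count_closed_form(self):
        mu, phi = 3.0, 0.4
        got = float(nb_log_density_continuous(0.0, mu, phi))
        assert np.isclose(got, (1 / phi) * np.log(1 / (1 + phi * mu)), rtol=1e-12)

    def test_matches_textbook_pmf_at_integers(self):
        # independent oracle: scipy's NB pmf with size 1/phi, prob a/(a+mu)
        ys = np.arange(0, 30)
        for mu in (0.5, 2.0, 20.0):
            for phi in (0.05, 0.5, 2.0):
                a = 1 / phi
                oracle = stats.nbinom.logpmf(ys, a, a / (a + mu))
                got = nb_log_density_continuous(ys.astype(float), mu, phi)
                assert np.allclose(got, oracle, rtol=0, atol=1e-10)

    def test_smooth_interpolation_between_integers(self):
        v2 = float(nb_log_density_continuous(2.0, 2.5, 0.5))
        v25 = float(nb_log_density_continuous(2.5, 2.5, 0.5))
        v3 = float(nb_log_density_continuous(3.0, 2.5, 0.5))
        assert min(v2, v3) < v25 <= max(v2, v3) + 1e-12


class TestFitOneGroup:
    def test_equal_offsets_give_exact_mean(self):
        for phi in (0.0, 0.2, 2.0):
            beta, mu, conv, _ = fit_one_group([[2.0, 4.0, 6.0]], np.zeros((1, 3)), phi)
            assert np.allclose(mu, 4.0, rtol=1e-12)
            assert conv.all()

    def test_all_zero_gene_gets_sentinel(self):
        beta, mu, conv, _ = fit_one_group([[0.0, 0.0]], np.zeros((1, 2)), 0.1)
        assert beta[0] == -np.inf
        assert np.array_equal(mu, [[0.0, 0.0]])

    def test_unequal_offsets_match_likelihood_maximization_oracle(self):
        y = np.array([[1.0, 4.0]])
        off = np.log(np.array([[1.0, 2.0]]))
        phi = 0.2
        beta, mu, conv, _ = fit_one_group(y, off, phi)

        def negll(b):
            m = np.exp(b + off[0])
            return -nb_log_density_continuous(y[0], m, phi).sum()

        # refine the 1-d maximizer by root-finding on a numerical gradient
        eps = 1e-6

        def grad(b):
            return (negll(b + eps) - negll(b - eps)) / (2 * eps)

        root = optimize.brentq(grad, -2.0, 3.0, xtol=1e-13)
        assert abs(beta[0] - root) < 1e-8

    def test_rejects_nonfinite_offsets(self):
        with pytest.raises(ValueError):
            fit_one_group([[1.0, 2.0]], [[np.inf, 0.0]], 0.1)


class TestFitLevenberg:
    def test_one_way_design_returns_group_means(self, rng):
        y = rng.poisson(20, size=(30, 6)).astype(float)
        X = cq.DesignMatrix.from_group(["A"] * 3 + ["B"] * 3)
        fit = fit_levenberg(y, X, np.zeros_like(y), 0.1)
        assert np.allclose(fit.fitted[:, :3], y[:, :3].mean(axis=1, keepdims=True))
        assert np.allclose(fit.fitted[:, 3:], y[:, 3:].mean(axis=1, keepdims=True))

    def test_matches_poisson_regression_oracle(self, rng):
        # phi = 0 with a continuous covariate: compare to statsmodels IRLS
        import statsmodels.api as sm

        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        y = rng.poisson(np.exp(1.5 + 0.4 * X[:, 1]), size=(40, 6)).astype(float)
        fit = fit_levenberg(y, X, np.zeros_like(y), 0.0)
        for g in range(40):
            oracle = sm.GLM(y[g], X, family=sm.families.Poisson()).fit()
            assert np.allclose(fit.coefficients[g], oracle.params, atol=1e-8)

    def test_deviance_non_increasing_across_iterations(self, rng):
        X = np.column_stack([np.ones(8), rng.normal(size=8), rng.normal(size=8)])
        mu = np.exp(rng.normal(2, 1, size=(100, 1)) + 0.5 * X[:, 1][None, :])
        y = rng.poisson(mu).astype(float)
        prev = None
        for k in range(1, 6):
            fit = fit_levenberg(y, X, np.zeros_like(y), 0.1, maxit=k)
            if prev is not None:
                assert np.all(fit.deviance <= prev + 1e-8)
            prev = fit.deviance

    def test_invariant_to_design_reparameterization(self, rng):
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1.0]])
        T = np.array([[2.0, 1.0], [0.5, 1.5]])  # invertible
        y = rng.poisson(15, size=(25, 6)).astype(float)
        f1 = fit_levenberg(y, X, np.zeros_like(y), 0.05)
        f2 = fit_levenberg(y, X @ T, np.zeros_like(y), 0.05)
        assert np.allclose(f1.fitted, f2.fitted, rtol=1e-6)
        assert np.allclose(f1.deviance, f2.deviance, rtol=1e-6)

    def test_all_zero_rows_flagged(self):
        y = np.zeros((2, 4))
        y[1] = [1, 2, 3, 4]
        fit = fit_levenberg(y, np.ones((4, 1)), np.zeros_like(y), 0.1)
        assert fit.all_zero[0] and not fit.all_zero[1]
        assert np.array_equal(fit.fitted[0], np.zeros(4))
        assert fit.deviance[0] == 0.0


class TestPriorCounts:
    def test_zero_prior_is_identity(self, small_dataset):
        aug, off = cq.add_prior_counts(small_dataset, 0.0)
        assert np.array_equal(aug, small_dataset.counts)

    def test_equal_els_gives_equal_priors(self):
        ds = cq.make_dataset(np.ones((3, 4)), lib_size=np.full(4, 100.0))
        aug, off = cq.add_prior_counts(ds, 0.5)
        assert np.allclose(aug - ds.counts, 0.5)
        assert np.allclose(off.expand(), np.log(101.0))

    def test_shrinkage_monotone_in_prior_count(self):
        # a zero-count contrast has finite logFC that shrinks with the prior
        counts = np.array([[0.0, 0.0, 20.0, 22.0]])
        ds = cq.make_dataset(counts, group=list("AABB"), lib_size=np.full(4, 100.0))
        dm = cq.DesignMatrix.from_group(ds.samples["group"])
        prev = np.inf
        for pc in (0.05, 0.125, 0.5, 1.0, 2.0):
            fit = cq.glm_fit(ds, dm, 0.1, prior_count=pc)
            lfc = abs(fit.coefficients_shrunk[0, 1] - fit.coefficients_shrunk[0, 0])
            assert np.isfinite(lfc)
            assert lfc < prev
            prev = lfc
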