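"""G-Wishart density, sampling, conjugacy, and normalizing constants."""

import numpy as np
import pytest

from scipy.stats import wishart

from bggm import (
    Graph,
    GWishartParams,
    PrecisionMatrix,
    ScatterMatrix,
    TimeSeriesData,
    gaussian_log_likelihood,
    gwishart_posterior_params,
    gwishart_sample,
    gwishart_unnorm_log_density,
    is_decomposable,
    log_normalizing_constant,
    scatter_matrix,
    simulate_timeseries,
)
from bggm.gwishart import _mc_log_norm_const


class TestDensity:
    def test_univariate_example(self):
        params = GWishartParams(3.0, np.array([[1.0]]), Graph.empty(1))
        K = PrecisionMatrix(np.array([[2.0]]))
        assert gwishart_unnorm_log_density(K, params) == pytest.approx(0.5 * np.log(2) - 1.0)

    def test_full_graph_matches_wishart(self, random_pd):
        """On a complete graph the distribution reduces to the ordinary Wishart
        with df delta + p - 1 and scale D^{-1} (scipy as independent route)."""
        p, delta = 3, 3.0
        D = random_pd(p)
        G = Graph.complete(p)
        params = GWishartParams(delta, D, G)
        log_z, se = log_normalizing_constant(params)
        assert se == 0.0
        K = PrecisionMatrix(random_pd(p))
        ours = gwishart_unnorm_log_density(K, params) - log_z
        scipy_ref = wishart(df=delta + p - 1, scale=np.linalg.inv(D)).logpdf(K.values)
        assert ours == pytest.approx(scipy_ref, abs=1e-9)

    def test_scaling_identity(self, random_pd):
        delta, p, c = 3.0, 3, 2.5
        D = random_pd(p)
        params = GWishartParams(delta, D, Graph.complete(p))
        K = PrecisionMatrix(random_pd(p))
        Kc = PrecisionMatrix(c * K.values)
        diff = gwishart_unnorm_log_density(Kc, params) - gwishart_unnorm_log_density(K, params)
        expected = 0.5 * (delta - 2) * p * np.log(c) - 0.5 * (c - 1) * np.sum(K.values * D)
        assert diff == pytest.approx(expected)

    def test_zero_pattern_violation_is_error(self):
        params = GWishartParams(3.0, np.eye(2), Graph.empty(2))
        with pytest.raises(ValueError, match="off the graph"):
            gwishart_unnorm_log_density(PrecisionMatrix(np.array([[2.0, 0.3], [0.3, 2.0]])),
                                        params)


class TestConjugateUpdate:
    def test_no_data_is_identity(self):
        params = GWishartParams(3.0, np.eye(2), Graph.complete(2))
        out = gwishart_posterior_params(params, ScatterMatrix(np.zeros((2, 2)), 0))
        assert out.delta == 3.0
        np.testing.assert_array_equal(out.D, params.D)

    def test_update_formula(self, rng):
        X = TimeSeriesData(rng.standard_normal((10, 3)))
        Sigma = scatter_matrix(X)
        params = GWishartParams(3.0, np.eye(3), Graph.complete(3))
        out = gwishart_posterior_params(params, Sigma)
        assert out.delta == 13.0
        np.testing.assert_allclose(out.D, np.eye(3) + Sigma.sigma)

    def test_sequential_additivity(self, rng):
        p = 3
        X1, X2 = rng.standard_normal((6, p)), rng.standard_normal((9, p))
        s1 = scatter_matrix(TimeSeriesData(X1))
        s2 = scatter_matrix(TimeSeriesData(X2))
        both = ScatterMatrix(s1.sigma + s2.sigma, s1.n + s2.n)
        params = GWishartParams(3.0, np.eye(p), Graph.complete(p))
        two_step = gwishart_posterior_params(gwishart_posterior_params(params, s1), s2)
        one_step = gwishart_posterior_params(params, both)
        assert two_step.delta == one_step.delta
        np.testing.assert_allclose(two_step.D, one_step.D)


class TestSampling:
    def test_empty_graph_gamma_marginals(self):
        params = GWishartParams(3.0, np.eye(3), Graph.empty(3))
        draws = np.stack([k.values for k in gwishart_sample(params, 4000, seed=1)])
        diag = draws[:, np.arange(3), np.arange(3)]
        # k_ii ~ Gamma(3/2, rate 1/2): mean 3, var 6
        se = np.sqrt(6.0 / diag.shape[0])
        assert np.all(np.abs(diag.mean(axis=0) - 3.0) < 3 * se)
        off = draws[:, 0, 1]
        assert np.all(off == 0.0)

    def test_full_graph_wishart_mean(self, random_pd):
        p = 3
        D = random_pd(p)
        params = GWishartParams(3.0, D, Graph.complete(p))
        draws = np.stack([k.values for k in gwishart_sample(params, 20_000, seed=2)])
        expected = (3.0 + p - 1) * np.linalg.inv(D)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-12)

    def test_support_and_determinism(self):
        G = Graph.from_bitstring("110001", 4)
        params = GWishartParams(3.0, np.eye(4), G)
        draws = gwishart_sample(params, 50, seed=7)
        nonedge = (G.adjacency == 0) & ~np.eye(4, dtype=bool)
        for k in draws:
            assert np.all(k.values[nonedge] == 0.0)
            assert np.linalg.eigvalsh(k.values).min() > 0
        again = gwishart_sample(params, 50, seed=7)
        np.testing.assert_array_equal(draws[10].values, again[10].values)

    def test_prior_reweighting_matches_posterior_sampler(self, rng):
        """Conjugacy both ways: prior draws importance-reweighted by the
        Gaussian likelihood reproduce the posterior-parameter sampler's mean."""
        p, n = 2, 20
        G = Graph.complete(p)
        prior = GWishartParams(3.0, np.eye(p), G)
        X = simulate_timeseries(PrecisionMatrix(np.array([[1.0, 0.3], [0.3, 1.0]])), n, rng)
        Sigma = scatter_matrix(X)
        post = gwishart_posterior_params(prior, Sigma)
        post_draws = np.stack([k.values for k in gwishart_sample(post, 20_000, seed=3)])
        prior_draws = gwishart_sample(prior, 200_000, seed=4)
        logw = np.array([gaussian_log_likelihood(k, Sigma) for k in prior_draws])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        weighted_mean = np.tensordot(w, np.stack([k.values for k in prior_draws]), axes=1)
        np.testing.assert_allclose(weighted_mean, post_draws.mean(axis=0), rtol=0.1)


class TestDecomposability:
    @pytest.mark.parametrize("bits, p, expected", [
        ("111", 3, True),        # triangle
        ("101101", 4, False),    # chordless 4-cycle 0-1-3-2-0
        ("000", 3, True),        # empty
        ("1" * 6, 4, True),      # complete
    ])
    def test_examples(self, bits, p, expected):
        assert is_decomposable(Graph.from_bitstring(bits, p)) is expected


class TestNormalizingConstant:
    def test_univariate(self):
        params = GWishartParams(3.0, np.array([[1.0]]), Graph.empty(1))
        log_z, se = log_normalizing_constant(params)
        assert se == 0.0
        assert log_z == pytest.approx(np.log(np.sqrt(2 * np.pi)))  # Gamma(3/2) 2^{3/2}

    def test_full_graph_closed_form(self, random_pd):
        """Clique factorization agrees with the multivariate-gamma Wishart
        constant in the (delta + p - 1, D^{-1}) parameterization."""
        p, delta = 4, 3.0
        D = random_pd(p)
        params = GWishartParams(delta, D, Graph.complete(p))
        log_z, _ = log_normalizing_constant(params)
        nu = delta + p - 1
        from scipy.special import multigammaln
        expected = (0.5 * nu * p * np.log(2) + multigammaln(0.5 * nu, p)
                    - 0.5 * nu * np.linalg.slogdet(D)[1])
        assert log_z == pytest.approx(expected)

    @pytest.mark.parametrize("bits", ["100", "110", "111"])
    def test_decomposable_matches_monte_carlo(self, bits, random_pd):
        G = Graph.from_bitstring(bits, 3)
        params = GWishartParams(3.0, random_pd(3), G)
        exact, _ = log_normalizing_constant(params)
        mc, se = _mc_log_norm_const(params, 200_000, np.random.default_rng(11))
        assert abs(exact - mc) < 3 * se + 1e-6

    def test_path_graph_example(self):
        G = Graph.from_bitstring("101", 3)  # path 0-1-2
        params = GWishartParams(3.0, np.eye(3), G)
        exact, se = log_normalizing_constant(params)
        assert se == 0.0
        mc, mc_se = _mc_log_norm_const(params, 100_000, np.random.default_rng(3))
        assert abs(exact - mc) < 3 * max(mc_se, 1e-9)

    def test_nondecomposable_two_estimators_agree(self):
        """The 4-cycle constant from two independent proposal scales."""
        G = Graph.from_bitstring("101101", 4)
        params = GWishartParams(3.0, np.eye(4), G)
        z1, se1 = log_normalizing_constant(params, mc_samples=150_000, seed=21)
        z2, se2 = log_normalizing_constant(params, mc_samples=150_000, seed=77)
        assert se1 > 0
        assert abs(z1 - z2) < 3 * np.hypot(se1, se2)

    def test_nondecomposable_needs_samples(self):
        G = Graph.from_bitstring("101101", 4)
        with pytest.raises(ValueError, match="mc_samples"):
            log_normalizing_constant(GWishartParams(3.0, np.eye(4), G), mc_samples=0)

    def test_kernel_integral_quadrature_p1(self):
        """exp(log Z) integrates the kernel (checked by quadrature, p = 1)."""
        from scipy.integrate import quad
        d, delta = 2.7, 3.0
        params = GWishartParams(delta, np.array([[d]]), Graph.empty(1))
        log_z, _ = log_normalizing_constant(params)
        val, _ = quad(lambda k: k ** ((delta - 2) / 2) * np.exp(-0.5 * k * d), 0, np.inf)
        assert log_z == pytest.approx(np.log(val), abs=1e-8)
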