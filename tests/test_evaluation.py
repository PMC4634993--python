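"""Error measures, posterior-shape diagnostics, summaries, and the exact
enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from bggm import (
    EdgePrior,
    Graph,
    GroundTruth,
    PartialCorrelationMatrix,
    PrecisionMatrix,
    TimeSeriesData,
    exact_small_p_posterior,
    map_probability,
    posterior_entropy,
    posterior_summaries,
    reconstruction_errors,
    scatter_matrix,
    simulate_timeseries,
    z_score,
)
from bggm.evaluation import UndefinedErrorScore, log_marginal_likelihood
from bggm.mcmc import PosteriorSamples


def _truth_3x3():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.5
    mask = np.zeros((3, 3), dtype=int)
    mask[0, 1] = mask[1, 0] = 1
    return GroundTruth(PartialCorrelationMatrix(r), mask)


def _samples_from_bits(bits_list, p=3):
    graphs = [Graph.from_bitstring(b, p) for b in bits_list]
    precisions = [PrecisionMatrix(np.eye(p) * 2 + g.adjacency * 0.5, g) for g in graphs]
    return PosteriorSamples(graphs, precisions, {"chain_id": np.zeros(len(graphs), int)})


class TestReconstructionErrors:
    def test_perfect_reconstruction(self):
        truth = _truth_3x3()
        scores = reconstruction_errors(truth, truth.R_star)
        assert (scores.eta, scores.eta_tp, scores.eta_tn) == (0.0, 0.0, 0.0)

    def test_hand_computed_fixture(self):
        truth = _truth_3x3()
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.3
        r[0, 2] = r[2, 0] = 0.1
        r[1, 2] = r[2, 1] = 0.1
        scores = reconstruction_errors(truth, PartialCorrelationMatrix(r))
        assert scores.eta == pytest.approx(0.4 / 3)
        assert scores.eta_tp == pytest.approx(0.2)
        assert scores.eta_tn == pytest.approx(0.1)

    def test_full_mask_undefined_tn(self):
        r = np.eye(2)
        mask = np.ones((2, 2), dtype=int) - np.eye(2, dtype=int)
        truth = GroundTruth(PartialCorrelationMatrix(r), mask)
        with pytest.raises(UndefinedErrorScore, match="non-edges"):
            reconstruction_errors(truth, truth.R_star)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_decomposition_identity(self, seed):
        """eta * #pairs == eta_tp * N_tp + eta_tn * N_tn exactly."""
        rng = np.random.default_rng(seed)
        p = 5
        mask = np.zeros((p, p), dtype=int)
        iu = np.triu_indices(p, 1)
        bits = rng.integers(0, 2, len(iu[0]))
        if bits.min() == bits.max():  # need both classes present
            bits[0], bits[-1] = 0, 1
        mask[iu] = bits
        mask = mask + mask.T
        r_star = np.eye(p) * 1.0
        vals = rng.uniform(-0.5, 0.5, len(iu[0])) * (bits == 1)
        r_star[iu] = vals
        r_star = r_star + r_star.T - np.diag(np.diag(r_star)) + np.eye(p) - np.eye(p)
        np.fill_diagonal(r_star, 1.0)
        truth = GroundTruth(PartialCorrelationMatrix(r_star), mask)
        r_est = np.eye(p)
        est_vals = rng.uniform(-0.5, 0.5, len(iu[0]))
        r_est[iu] = est_vals
        r_est = 0.5 * (r_est + r_est.T)
        np.fill_diagonal(r_est, 1.0)
        s = reconstruction_errors(truth, PartialCorrelationMatrix(r_est))
        n_pairs = p * (p - 1) / 2
        assert s.eta * n_pairs == pytest.approx(
            s.eta_tp * truth.n_tp + s.eta_tn * truth.n_tn, abs=1e-12)


class TestZScore:
    def test_point_at_mean_is_zero(self):
        assert z_score(2.0, [1.0, 2.0, 3.0]) == 0.0

    def test_unit_displacement(self, rng):
        samples = rng.normal(2.0, 1.0, 40_000)
        z = z_score(samples.mean() + samples.std(), samples)
        assert z == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_recomputation(self, rng):
        samples = rng.uniform(0, 1, 100)
        z = z_score(0.7, samples)
        assert z == pytest.approx((0.7 - samples.mean()) / samples.std(), abs=1e-12)

    def test_zero_spread(self):
        with pytest.raises(ValueError, match="spread"):
            z_score(1.0, [2.0, 2.0])


class TestEntropyAndMap:
    def test_degenerate_sample(self):
        s = _samples_from_bits(["101"] * 10)
        assert posterior_entropy(s) == 0.0
        _, prob, tied = map_probability(s)
        assert prob == 1.0 and len(tied) == 1

    def test_uniform_over_eight_graphs(self):
        bits = [format(i, "03b") for i in range(8)]
        s = _samples_from_bits(bits * 5)
        assert posterior_entropy(s) == pytest.approx(3.0)

    def test_three_quarters_split(self):
        s = _samples_from_bits(["101"] * 3 + ["000"])
        assert posterior_entropy(s) == pytest.approx(0.8112781244591328)

    def test_map_ties_reported_in_first_seen_order(self):
        s = _samples_from_bits(["010", "101", "010", "101"])
        modal, prob, tied = map_probability(s)
        assert prob == 0.25 * 2
        assert modal.to_bitstring() == "010"
        assert [g.to_bitstring() for g in tied] == ["010", "101"]

    def test_modal_graph_frequencies(self):
        s = _samples_from_bits(["111"] * 6 + ["000"] * 3 + ["100"])
        modal, prob, _ = map_probability(s)
        assert modal.to_bitstring() == "111"
        assert prob == 0.6

    def test_entropy_bounds(self, rng):
        bits = [format(rng.integers(0, 8), "03b") for _ in range(50)]
        h = posterior_entropy(_samples_from_bits(bits))
        assert 0.0 <= h <= np.log2(50)


class TestPosteriorSummaries:
    def test_single_draw(self):
        s = _samples_from_bits(["101"])
        out = posterior_summaries(s)
        assert set(np.unique(out.edge_probabilities)) <= {0.0, 1.0}
        assert np.all(out.partial_correlation_variance == 0.0)

    def test_empty_and_full(self):
        s = _samples_from_bits(["000", "111"])
        out = posterior_summaries(s)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(out.edge_probabilities[iu], 0.5)
        assert out.mean_density == 0.5

    def test_matches_hand_computation(self):
        from bggm import precision_to_partial

        s = _samples_from_bits(["100", "110", "000", "100"])
        out = posterior_summaries(s)
        partials = np.stack([precision_to_partial(k).values for k in s.precisions])
        np.testing.assert_allclose(out.mean_partial_correlations, partials.mean(axis=0))
        np.testing.assert_allclose(out.partial_correlation_variance, partials.var(axis=0))
        assert out.edge_probabilities[0, 1] == 0.75
        assert out.mean_density == pytest.approx((1 + 2 + 0 + 1) / (4 * 3))


class TestEnumerationOracle:
    def test_empty_graph_evidence_closed_form(self, rng):
        """Independent oracle for the fully disconnected graph: the marginal
        likelihood factorizes into univariate Gamma integrals."""
        p, n = 3, 12
        X = TimeSeriesData(rng.standard_normal((n, p)))
        Sigma = scatter_matrix(X)
        ours = log_marginal_likelihood(Sigma, Graph.empty(p))
        delta = 3.0
        expected = 0.0
        for i in range(p):
            s_ii = Sigma.sigma[i, i]
            expected += (-0.5 * n * np.log(2 * np.pi)
                         + 0.5 * delta * np.log(0.5) + gammaln(0.5 * (delta + n))
                         - gammaln(0.5 * delta)
                         - 0.5 * (delta + n) * np.log(0.5 * (1.0 + s_ii)))
        assert ours == pytest.approx(expected, abs=1e-9)

    def test_full_graph_evidence_monte_carlo(self, rng):
        """Independent route: average the Gaussian likelihood over scipy
        Wishart prior draws (no normalizing-constant code involved)."""
        from scipy.stats import wishart

        p, n = 2, 8
        K_true = np.array([[1.0, 0.3], [0.3, 1.0]])
        X = simulate_timeseries(PrecisionMatrix(K_true), n, rng)
        Sigma = scatter_matrix(X)
        ours = log_marginal_likelihood(Sigma, Graph.complete(p))
        # prior W_G(3, I) on the complete graph == Wishart(df 4, scale I)
        W = wishart(df=4, scale=np.eye(p)).rvs(1_000_000, random_state=123)
        _, logdet = np.linalg.slogdet(W)
        tr = np.einsum("mij,ji->m", W, Sigma.sigma)
        logl = 0.5 * n * logdet - 0.5 * tr - 0.5 * n * p * np.log(2 * np.pi)
        shift = logl.max()
        w = np.exp(logl - shift)
        mc = shift + np.log(w.mean())
        se = w.std() / (w.mean() * np.sqrt(w.size))
        assert abs(ours - mc) < 3 * se + 1e-4

    def test_exchangeable_columns_give_equal_edge_probabilities(self, rng):
        p, n = 3, 30
        col = rng.standard_normal((n, 1))
        X = TimeSeriesData(col + 0.8 * rng.standard_normal((n, p)))
        probs = exact_small_p_posterior(X, EdgePrior.flat(p, 0.5))
        iu = np.triu_indices(p, 1)
        # columns are exchangeable in distribution but not numerically equal;
        # only symmetry of the machinery is checked here: permute the data
        perm = np.array([2, 0, 1])
        probs_perm = exact_small_p_posterior(
            TimeSeriesData(X.values[:, perm]), EdgePrior.flat(p, 0.5))
        np.testing.assert_allclose(probs_perm, probs[np.ix_(perm, perm)], atol=1e-10)

    def test_p1_has_no_edges(self):
        with pytest.raises(ValueError):
            # a single column is not a valid multivariate time series
            TimeSeriesData(np.ones((5, 1)))

    def test_posterior_normalization_and_p_limit(self, rng):
        X = TimeSeriesData(rng.standard_normal((20, 5)))
        with pytest.raises(ValueError, match="p <= 4"):
            exact_small_p_posterior(X, EdgePrior.flat(5, 0.5))

    def test_hard_prior_zero_excludes_edge(self, rng):
        X = TimeSeriesData(rng.standard_normal((30, 3)))
        theta = np.full((3, 3), 0.5)
        theta[0, 1] = theta[1, 0] = 0.0
        probs = exact_small_p_posterior(X, EdgePrior(theta))
        assert probs[0, 1] == 0.0
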