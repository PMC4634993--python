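"""Joint (G, K) sampler: support invariants, prior reproduction, hard
constraints, streamline bookkeeping, and convergence reporting."""

import numpy as np
import pytest

from bggm import (
    EdgePrior,
    Graph,
    McmcConfig,
    StreamlineCounts,
    convergence_report,
    dirmult_log_likelihood,
    sample_joint_posterior,
)
from bggm.mcmc import PosteriorSamples, _StreamlineTerms, sample_prior_only


def _quick_cfg(**kw):
    base = dict(n_iterations=2000, burn_in=500, thin_to=300, n_chains=1, seed=9)
    base.update(kw)
    return McmcConfig(**base)


class TestSupportInvariants:
    def test_every_draw_respects_graph_and_pd(self, p3_fixture):
        samples = sample_joint_posterior(p3_fixture["X"], p3_fixture["theta"],
                                         cfg=_quick_cfg())
        for g, k in zip(samples.graphs, samples.precisions):
            off = (g.adjacency == 0) & ~np.eye(3, dtype=bool)
            assert np.all(k.values[off] == 0.0)
            assert np.linalg.eigvalsh(k.values).min() > 0

    def test_reproducible_given_seed(self, p3_fixture):
        a = sample_joint_posterior(p3_fixture["X"], p3_fixture["theta"], cfg=_quick_cfg())
        b = sample_joint_posterior(p3_fixture["X"], p3_fixture["theta"], cfg=_quick_cfg())
        assert a.bitstrings() == b.bitstrings()
        np.testing.assert_array_equal(a.precision_stack(), b.precision_stack())

    def test_default_retained_length_is_1000_per_chain(self, p3_fixture):
        cfg = McmcConfig(n_iterations=3000, burn_in=500, n_chains=1, seed=2)
        samples = sample_joint_posterior(p3_fixture["X"], p3_fixture["theta"], cfg=cfg)
        assert cfg.thin_to == 1000
        assert len(samples) == 1000


class TestPriorReproduction:
    def test_flat_data_recovers_edge_prior(self):
        """With no data (scatter 0) the graph marginal is the Bernoulli prior:
        a detailed-balance smoke test."""
        p = 3
        theta = np.zeros((p, p))
        theta[0, 1], theta[0, 2], theta[1, 2] = 0.25, 0.5, 0.75
        prior = EdgePrior(theta)
        cfg = McmcConfig(n_iterations=30_000, burn_in=3000, thin_to=6000,
                         n_chains=1, seed=31)
        samples = sample_prior_only(p, prior, cfg=cfg)
        probs = samples.edge_probabilities()
        iu = np.triu_indices(p, 1)
        # thinned draws are not independent; allow 3x the binomial SE at an
        # effective sample size of a quarter of the retained draws
        se = np.sqrt(0.25 / (cfg.thin_to / 4))
        assert np.all(np.abs(probs[iu] - prior.theta[iu]) < 3 * se)


class TestHardConstraints:
    def test_zero_prior_forces_empty_graph(self, p3_fixture):
        theta = EdgePrior(np.zeros((3, 3)))
        samples = sample_joint_posterior(p3_fixture["X"], theta, cfg=_quick_cfg())
        for g, k in zip(samples.graphs, samples.precisions):
            assert g.n_edges == 0
            assert np.all(k.values[~np.eye(3, dtype=bool)] == 0.0)

    def test_one_prior_forces_edge_in_every_sample(self, p3_fixture):
        theta = np.full((3, 3), 0.5)
        theta[0, 2] = theta[2, 0] = 1.0
        theta[0, 1] = theta[1, 0] = 0.0
        samples = sample_joint_posterior(p3_fixture["X"], EdgePrior(theta), cfg=_quick_cfg())
        adj = samples.adjacency_stack()
        assert np.all(adj[:, 0, 2] == 1)
        assert np.all(adj[:, 0, 1] == 0)


class TestStreamlineTerms:
    def test_flip_delta_matches_full_recomputation(self, rng):
        p = 5
        counts = rng.integers(0, 30, (p, p))
        np.fill_diagonal(counts, 0)
        S = StreamlineCounts(counts)
        terms = _StreamlineTerms(S, 1.0, 0.5)
        adj = np.zeros((p, p), dtype=np.int8)
        adj[1, 3] = adj[3, 1] = 1
        for (i, j) in [(0, 1), (1, 3), (2, 4)]:
            flipped = adj.copy()
            flipped[i, j] = flipped[j, i] = 1 - flipped[i, j]
            expected = (dirmult_log_likelihood(S, Graph(flipped), 1.0, 0.5)
                        - dirmult_log_likelihood(S, Graph(adj), 1.0, 0.5))
            assert terms.flip_delta(adj, i, j) == pytest.approx(expected, abs=1e-9)

    def test_alpha_equals_beta_contributes_nothing(self, rng):
        p = 4
        counts = rng.integers(0, 20, (p, p))
        np.fill_diagonal(counts, 0)
        terms = _StreamlineTerms(StreamlineCounts(counts), 0.8, 0.8)
        adj = np.zeros((p, p), dtype=np.int8)
        for (i, j) in [(0, 1), (2, 3), (1, 2)]:
            assert terms.flip_delta(adj, i, j) == pytest.approx(0.0, abs=1e-10)


class TestConfigValidation:
    def test_thin_exceeding_kept_iterations(self):
        with pytest.raises(ValueError, match="thin_to"):
            McmcConfig(n_iterations=100, burn_in=50, thin_to=60, seed=1).validate()

    def test_label_mismatch_in_fusion(self, p3_fixture):
        from bggm import sample_fused_posterior

        counts = np.zeros((3, 3), dtype=int)
        S = StreamlineCounts(counts, ("a", "b", "c"))
        with pytest.raises(ValueError, match="labels"):
            sample_fused_posterior(p3_fixture["X"], S, p3_fixture["theta"],
                                   cfg=_quick_cfg())


class TestConvergenceReport:
    def _samples_from(self, graphs, chain):
        from bggm import PrecisionMatrix

        precisions = [PrecisionMatrix(np.eye(g.p) * 2
                                      + g.adjacency * 0.5, g) for g in graphs]
        return PosteriorSamples(graphs, precisions,
                                {"chain_id": np.full(len(graphs), chain)})

    def test_identical_chains_pass(self):
        graphs = [Graph.from_bitstring("101", 3)] * 20
        report = convergence_report([self._samples_from(graphs, 0),
                                     self._samples_from(graphs, 1)])
        assert report.max_discrepancy == 0.0
        assert report.passed

    def test_disjoint_chains_fail(self):
        empty = [Graph.empty(3)] * 20
        full = [Graph.complete(3)] * 20
        report = convergence_report([self._samples_from(empty, 0),
                                     self._samples_from(full, 1)])
        assert report.max_discrepancy == 1.0
        assert not report.passed

    def test_single_chain_rejected(self):
        graphs = [Graph.empty(3)] * 5
        with pytest.raises(ValueError, match="2 chains"):
            convergence_report([self._samples_from(graphs, 0)])
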