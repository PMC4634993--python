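"""Reconstruction-error measures, posterior-shape diagnostics, posterior
summaries, and an exact small-p enumeration oracle.

Error measures compare a recovered partial-correlation matrix R against a
ground truth R*: with Gamma = |R* - R| elementwise,

* eta    — mean absolute error over all p(p-1)/2 pairs,
* eta_tp — mean over pairs with a true edge (N_tp of them),
* eta_tn — mean over pairs without one (N_tn of them),

so that ``eta * p(p-1)/2 = eta_tp * N_tp + eta_tn * N_tn`` exactly.  A z-score
standardizes a point estimate's eta against the distribution of eta obtained by
applying the same measure to each posterior draw.

Posterior-shape diagnostics are plug-in estimates over the discrete graph
marginal of the retained draws: the entropy (bits) of the empirical graph
frequencies, and the empirical frequency of the modal (maximum a posteriori)
graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data import (
    Graph,
    PartialCorrelationMatrix,
    ScatterMatrix,
    TimeSeriesData,
    precision_to_partial,
    scatter_matrix,
)
from .gwishart import GWishartParams, log_normalizing_constant
from .mcmc import PosteriorSamples, PrecisionPrior
from .priors import EdgePrior, graph_log_prior

__all__ = [
    "GroundTruth",
    "ErrorScores",
    "reconstruction_errors",
    "z_score",
    "eta_distribution",
    "posterior_entropy",
    "map_probability",
    "posterior_summaries",
    "PosteriorSummary",
    "exact_small_p_posterior",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class UndefinedErrorScore(ValueError):
    """Raised when an error measure's reference set (true edges or true
    non-edges) is empty, leaving the score undefined."""


@dataclass(frozen=True)
class GroundTruth:
    """True partial correlations R* and the binary edge mask T of the
    generating network (undirected; symmetrized on construction)."""

    R_star: PartialCorrelationMatrix
    T_mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.T_mask)
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("ground-truth mask must be binary")
        mask = mask.astype(np.int8)
        mask = np.maximum(mask, mask.T)  # directionality in the truth is ignored
        np.fill_diagonal(mask, 0)
        if mask.shape != self.R_star.values.shape:
            raise ValueError("mask and R* dimensions do not match")
        off = ~np.eye(mask.shape[0], dtype=bool)
        if np.any((self.R_star.values != 0) & (mask == 0) & off):
            raise ValueError("R* has a nonzero partial correlation where the mask has no edge")
        object.__setattr__(self, "T_mask", mask)

    @property
    def p(self) -> int:
        return self.T_mask.shape[0]

    @property
    def n_tp(self) -> int:
        return int(self.T_mask[np.triu_indices(self.p, k=1)].sum())

    @property
    def n_tn(self) -> int:
        return self.p * (self.p - 1) // 2 - self.n_tp


@dataclass(frozen=True)
class ErrorScores:
    eta: float
    eta_tp: float
    eta_tn: float


def reconstruction_errors(truth: GroundTruth, R: PartialCorrelationMatrix) -> ErrorScores:
    """Total, true-positive and true-negative mean absolute errors of R
    against the ground truth."""
    if truth.p != R.p:
        raise ValueError("dimension mismatch between truth and estimate")
    iu = np.triu_indices(truth.p, k=1)
    gamma = np.abs(truth.R_star.values - R.values)[iu]
    mask = truth.T_mask[iu]
    if truth.n_tp == 0:
        raise UndefinedErrorScore("no true edges: eta_tp is undefined")
    if truth.n_tn == 0:
        raise UndefinedErrorScore("no true non-edges: eta_tn is undefined")
    eta = float(gamma.mean())
    eta_tp = float(gamma[mask == 1].mean())
    eta_tn = float(gamma[mask == 0].mean())
    return ErrorScores(eta, eta_tp, eta_tn)


def z_score(eta_point: float, eta_samples: np.ndarray | list[float]) -> float:
    """Standardized score of a point estimate's error against the posterior
    error distribution: ``(eta_point - mean) / sd``."""
    samples = np.asarray(eta_samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 posterior error samples")
    sd = float(samples.std(ddof=0))
    if sd == 0:
        raise ValueError("posterior error samples have zero spread")
    return (float(eta_point) - float(samples.mean())) / sd


def eta_distribution(truth: GroundTruth, samples: PosteriorSamples) -> np.ndarray:
    """Total reconstruction error of each retained draw's partial-correlation
    transform: the posterior distribution P(eta)."""
    return np.array([
        reconstruction_errors(truth, precision_to_partial(k)).eta
        for k in samples.precisions
    ])


def _graph_frequencies(samples: PosteriorSamples) -> np.ndarray:
    _, counts = np.unique(np.array(samples.bitstrings()), return_counts=True)
    return counts / counts.sum()


def posterior_entropy(samples: PosteriorSamples) -> float:
    """Plug-in entropy (bits) of the empirical graph frequencies."""
    if len(samples) == 0:
        raise ValueError("empty posterior sample")
    f = _graph_frequencies(samples)
    return float(-(f * np.log2(f)).sum())


def map_probability(samples: PosteriorSamples) -> tuple[Graph, float, list[Graph]]:
    """Modal graph and its empirical frequency.

    Returns ``(modal_graph, frequency, tied_graphs)``; ties are broken by first
    occurrence in the chain, with every tied graph reported.
    """
    if len(samples) == 0:
        raise ValueError("empty posterior sample")
    bits = samples.bitstrings()
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for idx, b in enumerate(bits):
        counts[b] = counts.get(b, 0) + 1
        first_seen.setdefault(b, idx)
    best = max(counts.values())
    tied = sorted((b for b, c in counts.items() if c == best), key=first_seen.get)
    p = samples.p
    modal = Graph.from_bitstring(tied[0], p)
    return modal, best / len(bits), [Graph.from_bitstring(b, p) for b in tied]


@dataclass(frozen=True)
class PosteriorSummary:
    edge_probabilities: np.ndarray
    mean_partial_correlations: np.ndarray
    partial_correlation_variance: np.ndarray
    mean_density: float


def posterior_summaries(samples: PosteriorSamples) -> PosteriorSummary:
    """Edge-inclusion probabilities, mean and per-edge variance of the partial
    correlations (transforming each draw first), and mean graph density."""
    if len(samples) == 0:
        raise ValueError("empty posterior sample")
    probs = samples.edge_probabilities()
    partials = np.stack([precision_to_partial(k).values for k in samples.precisions])
    mean_r = partials.mean(axis=0)
    var_r = partials.var(axis=0)
    iu = np.triu_indices(samples.p, k=1)
    density = float(samples.adjacency_stack()[:, iu[0], iu[1]].mean())
    return PosteriorSummary(probs, mean_r, var_r, density)


# ---------------------------------------------------------------------------
# exact enumeration oracle


def log_marginal_likelihood(
    Sigma: ScatterMatrix,
    G: Graph,
    prior: PrecisionPrior = PrecisionPrior(),
    mc_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Log evidence ``P(X | G)`` by integrating the precision analytically:
    ``(2 pi)^(-np/2) Z_G(delta + n, D + Sigma) / Z_G(delta, D)``.

    Exact for decomposable graphs; Monte-Carlo constants otherwise.
    """
    D = prior.scale_for(Sigma.p)
    prior_params = GWishartParams(prior.delta, D, G)
    post_params = GWishartParams(prior.delta + Sigma.n, D + Sigma.sigma, G)
    log_z_prior, _ = log_normalizing_constant(prior_params, mc_samples, seed)
    log_z_post, _ = log_normalizing_constant(post_params, mc_samples, seed + 1)
    return -0.5 * Sigma.n * Sigma.p * LOG_2PI + log_z_post - log_z_prior


def exact_small_p_posterior(
    X: TimeSeriesData,
    theta: EdgePrior,
    prior: PrecisionPrior = PrecisionPrior(),
    max_p: int = 4,
    mc_samples: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Exact posterior edge probabilities by enumerating all graphs on p nodes.

    Every graph's marginal likelihood is combined with the Bernoulli graph
    prior and normalized.  Decomposable graphs use closed-form normalizing
    constants; the (few) non-decomposable graphs at p = 4 use Monte-Carlo
    constants with ``mc_samples`` draws.  Intended as a test oracle for p <= 4:
    the number of graphs grows as 2^(p(p-1)/2).
    """
    p = X.p
    if p > max_p:
        raise ValueError(f"enumeration over 2^(p(p-1)/2) graphs is limited to p <= {max_p}")
    Sigma = scatter_matrix(X)
    iu = np.triu_indices(p, k=1)
    m = len(iu[0])
    log_weights = np.empty(2 ** m)
    adjacencies = []
    for idx, bits in enumerate(itertools.product((0, 1), repeat=m)):
        adj = np.zeros((p, p), dtype=np.int8)
        adj[iu] = bits
        G = Graph(adj + adj.T)
        adjacencies.append(G.adjacency)
        lp = graph_log_prior(G, theta)
        if np.isneginf(lp):
            log_weights[idx] = -np.inf
            continue
        log_weights[idx] = lp + log_marginal_likelihood(
            Sigma, G, prior, mc_samples=mc_samples, seed=seed + idx
        )
    log_weights -= log_weights.max()
    w = np.exp(log_weights)
    w /= w.sum()
    probs = np.tensordot(w, np.stack(adjacencies).astype(float), axes=1)
    np.fill_diagonal(probs, 0.0)
    return probs
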