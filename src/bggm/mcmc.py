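"""Joint MCMC over the conditional-independence graph and the precision matrix.

The sampler targets ``P(G, K | X) ∝ P(X | K) P(K | G) P(G)``, optionally
multiplied by a Dirichlet-multinomial streamline likelihood ``P(S | G)``.

One iteration consists of:

1. a single-edge flip proposed uniformly over the free (not hard-constrained)
   pairs, accepted through a double-conditional exchange step: conditioning on
   the remainder of K, the integral over the edge element is a closed-form
   Gaussian factor, and the intractable ratio of G-Wishart prior constants is
   replaced by the same factor evaluated on an auxiliary precision drawn from
   the prior under the *proposed* graph, so the constants cancel exactly;
2. the conjugate update ``K | G ~ W_G(delta + n, D + Sigma)``, applied as
   exact clique-block Gibbs sweeps.

Edge-prior entries of exactly 0 or 1 are hard constraints: those pairs are
never proposed (edges with prior 1 are inserted at initialization and remain).

Chains are reproducible given the config seed; retained draws are uniformly
thinned post-burn-in to ``thin_to`` samples per chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import Graph, PrecisionMatrix, ScatterMatrix, TimeSeriesData, scatter_matrix
from .fusion import StreamlineCounts
from .gwishart import _maximal_cliques
from .priors import EdgePrior

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "PrecisionPrior",
    "ConvergenceReport",
    "sample_joint_posterior",
    "sample_fused_posterior",
    "convergence_report",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PrecisionPrior:
    """G-Wishart hyperparameters shared by all graphs: df delta and scale D.

    Defaults to the vague choice delta = 3, D = identity.
    """

    delta: float = 3.0
    D: np.ndarray | None = None

    def scale_for(self, p: int) -> np.ndarray:
        if self.D is None:
            return np.eye(p)
        D = np.asarray(self.D, dtype=float)
        if D.shape != (p, p):
            raise ValueError(f"prior scale D has shape {D.shape}, expected ({p}, {p})")
        return 0.5 * (D + D.T)


@dataclass(frozen=True)
class McmcConfig:
    """Chain lengths and bookkeeping. ``burn_in`` defaults to 20% of iterations."""

    n_iterations: int = 50_000
    burn_in: int | None = None
    thin_to: int = 1000
    n_chains: int = 2
    seed: int = 0
    gibbs_sweeps: int = 2

    def resolved_burn_in(self) -> int:
        b = self.burn_in if self.burn_in is not None else self.n_iterations // 5
        if b < 0 or b >= self.n_iterations:
            raise ValueError("burn-in must lie in [0, n_iterations)")
        return b

    def validate(self) -> None:
        if self.n_iterations < 1 or self.thin_to < 1 or self.n_chains < 1:
            raise ValueError("n_iterations, thin_to and n_chains must be positive")
        kept = self.n_iterations - self.resolved_burn_in()
        if self.thin_to > kept:
            raise ValueError(
                f"thin_to={self.thin_to} exceeds the {kept} post-burn-in iterations"
            )


@dataclass
class PosteriorSamples:
    """Paired, thinned posterior draws of (G, K) with chain provenance."""

    graphs: list[Graph]
    precisions: list[PrecisionMatrix]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.graphs) != len(self.precisions):
            raise ValueError("graphs and precisions must have equal length")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def p(self) -> int:
        return self.graphs[0].p

    def adjacency_stack(self) -> np.ndarray:
        return np.stack([g.adjacency for g in self.graphs])

    def precision_stack(self) -> np.ndarray:
        return np.stack([k.values for k in self.precisions])

    def edge_probabilities(self) -> np.ndarray:
        """Fraction of retained draws in which each edge is present."""
        probs = self.adjacency_stack().mean(axis=0)
        np.fill_diagonal(probs, 0.0)
        return probs

    def bitstrings(self) -> list[str]:
        return [g.to_bitstring() for g in self.graphs]

    def by_chain(self) -> list["PosteriorSamples"]:
        ids = np.asarray(self.meta.get("chain_id", np.zeros(len(self), dtype=int)))
        out = []
        for cid in np.unique(ids):
            keep = np.flatnonzero(ids == cid)
            meta = dict(self.meta)
            meta["chain_id"] = ids[keep]
            out.append(PosteriorSamples(
                [self.graphs[i] for i in keep],
                [self.precisions[i] for i in keep],
                meta,
            ))
        return out


@dataclass(frozen=True)
class ConvergenceReport:
    """Cross-chain agreement of per-edge inclusion probabilities."""

    max_discrepancy: float
    per_edge: np.ndarray
    threshold: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (f"convergence {status}: max per-edge inclusion-probability "
                f"discrepancy {self.max_discrepancy:.4f} (threshold {self.threshold})")


# ---------------------------------------------------------------------------
# streamline likelihood bookkeeping (O(1) per edge flip)


class _StreamlineTerms:
    """Precomputed pieces of the Dirichlet-multinomial log-likelihood so that
    the change from flipping one edge costs O(1)."""

    def __init__(self, S: StreamlineCounts, alpha: float, beta: float):
        counts = S.counts.astype(float)
        p = S.p
        self.p = p
        self.ga = gammaln(counts + alpha) - gammaln(alpha)  # per-cell edge term
        self.gb = gammaln(counts + beta) - gammaln(beta)    # per-cell non-edge term
        row_tot = counts.sum(axis=1)
        ks = np.arange(p)  # possible edge degrees of a row
        conc_tot = alpha * ks[None, :] + beta * (p - 1 - ks[None, :])
        self.lgA = gammaln(conc_tot) - gammaln(conc_tot + row_tot[:, None])

    def flip_delta(self, adj: np.ndarray, i: int, j: int) -> float:
        """Log-likelihood change from flipping edge (i, j) in ``adj``."""
        sign = -1.0 if adj[i, j] else 1.0  # +1 when adding the edge
        delta = 0.0
        for r, c in ((i, j), (j, i)):
            k = int(adj[r].sum())
            k_new = k + (1 if sign > 0 else -1)
            delta += sign * (self.ga[r, c] - self.gb[r, c])
            delta += self.lgA[r, k_new] - self.lgA[r, k]
        return delta


# ---------------------------------------------------------------------------
# fast per-graph machinery
#
# The chain spends nearly all its time in small-matrix linear algebra, so the
# per-graph index structures (completion neighborhoods, maximal cliques and
# their complements) and the Cholesky factors of the two fixed scale matrices
# (prior D and posterior D + Sigma) are precomputed and cached by adjacency.


class _ScaleInfo:
    """A fixed G-Wishart scale matrix with cached factorizations."""

    def __init__(self, B: np.ndarray, df: float):
        self.B = B
        self.df = df  # the delta-style degrees of freedom
        C = np.linalg.cholesky(B)
        self.M = np.linalg.solve(C.T, np.eye(B.shape[0]))  # M M^T = B^{-1}
        self._block_M: dict[bytes, np.ndarray] = {}

    def block_M(self, c: np.ndarray) -> np.ndarray:
        key = c.tobytes()
        m = self._block_M.get(key)
        if m is None:
            C = np.linalg.cholesky(self.B[np.ix_(c, c)])
            m = np.linalg.solve(C.T, np.eye(c.size))
            self._block_M[key] = m
        return m


def _wishart_root(df: float, M: np.ndarray, rng: np.random.Generator,
                  tril: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Return M @ A with A the Bartlett factor, so (MA)(MA)^T ~ Wishart(df, M M^T)."""
    m = M.shape[0]
    A = np.zeros((m, m))
    if tril[0].size:
        A[tril] = rng.standard_normal(tril[0].size)
    A[np.arange(m), np.arange(m)] = np.sqrt(rng.chisquare(df - np.arange(m)))
    return M @ A


class _GraphCache:
    """Index structures for one adjacency pattern."""

    def __init__(self, adj: np.ndarray):
        p = adj.shape[0]
        self.p = p
        self.neighbors = [np.flatnonzero(adj[j]) for j in range(p)]
        self.others = [np.flatnonzero(np.arange(p) != j) for j in range(p)]
        self.nonedge = (adj == 0) & ~np.eye(p, dtype=bool)
        cliques = _maximal_cliques(adj)
        self.cliques = []
        for c in cliques:
            rest = np.setdiff1d(np.arange(p), c, assume_unique=True)
            tril = np.tril_indices(c.size, k=-1)
            self.cliques.append((c, rest, np.ix_(c, c), np.ix_(rest, rest),
                                 np.ix_(rest, c), np.ix_(c, rest), tril))


def _gibbs_sweeps_fast(K: np.ndarray, cache: _GraphCache, scale: _ScaleInfo,
                       sweeps: int, rng: np.random.Generator) -> None:
    """In-place clique-block Gibbs sweeps targeting W_G(scale.df, scale.B)."""
    for _ in range(sweeps):
        for c, rest, ix_cc, ix_rr, ix_rc, ix_cr, tril in cache.cliques:
            if rest.size:
                sol = np.linalg.solve(K[ix_rr], K[ix_rc])
                Mpart = K[ix_cr] @ sol
            else:
                Mpart = 0.0
            root = _wishart_root(scale.df + c.size - 1, scale.block_M(c), rng, tril)
            block = root @ root.T + Mpart
            K[ix_cc] = 0.5 * (block + block.T)


def _direct_draw(cache: _GraphCache, scale: _ScaleInfo, correction_sweeps: int,
                 rng: np.random.Generator,
                 full_tril: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """One (near-)independent draw from W_G via the direct sampler, refined by
    block-Gibbs correction sweeps."""
    p = cache.p
    root = _wishart_root(scale.df + p - 1, scale.M, rng, full_tril)
    W = root @ root.T
    n_edges = int(sum(nb.size for nb in cache.neighbors)) // 2
    if n_edges == p * (p - 1) // 2:
        return W
    if n_edges == 0:
        out = np.zeros((p, p))
        out[np.arange(p), np.arange(p)] = (
            rng.gamma(shape=0.5 * scale.df, size=p) * 2.0 / np.diag(scale.B)
        )
        return out
    sigma = np.linalg.inv(W)
    omega = sigma.copy()
    tol = 1e-9 * float(np.abs(sigma).max())
    # ill-conditioned base draws occasionally need a few thousand sweeps
    for _ in range(5000):
        delta_max = 0.0
        for j in range(p):
            nb = cache.neighbors[j]
            oth = cache.others[j]
            if nb.size == 0:
                new_col = np.zeros(p - 1)
            else:
                beta = np.linalg.solve(omega[np.ix_(nb, nb)], sigma[nb, j])
                new_col = omega[np.ix_(oth, nb)] @ beta
            delta_max = max(delta_max, float(np.abs(omega[oth, j] - new_col).max()))
            omega[oth, j] = new_col
            omega[j, oth] = new_col
        if delta_max <= tol:
            break
    else:
        raise RuntimeError("graph completion did not converge within 5000 iterations")
    K = np.linalg.inv(omega)
    if correction_sweeps > 0:
        _gibbs_sweeps_fast(K, cache, scale, correction_sweeps, rng)
    K[cache.nonedge] = 0.0
    return 0.5 * (K + K.T)


def _edge_conditional(K: np.ndarray, B: np.ndarray, i: int, j: int
                      ) -> tuple[float, float, float, float, float, float]:
    """Conditional law of the edge element k_ij given the rest of K.

    Writing the Schur complement of row/column j as ``s = k_jj - q(k_ij)`` with
    ``q(k) = alpha k^2 + 2 beta k + gamma`` (alpha, beta, gamma determined by
    the remaining entries), the target kernel in ``k = k_ij`` at fixed s is
    proportional to ``exp(-(b_jj alpha k^2 + 2 (b_ij + b_jj beta) k) / 2)``:
    a Gaussian with variance ``s2 = 1 / (b_jj alpha)`` and mean
    ``mu = -(b_ij + b_jj beta) s2``.  Integrating over k (edge present) versus
    evaluating at k = 0 (edge absent) gives the conditional factor
    ``sqrt(2 pi s2) exp(mu^2 / (2 s2))``.

    Returns ``(log_factor, mu, s2, alpha, beta, gamma)``.
    """
    p = K.shape[0]
    idx = np.arange(p) != j
    Kmm = K[np.ix_(idx, idx)]
    k0 = K[idx, j].copy()
    pos_i = i if i < j else i - 1
    k0[pos_i] = 0.0
    rhs = np.zeros((p - 1, 2))
    rhs[pos_i, 0] = 1.0
    rhs[:, 1] = k0
    x = np.linalg.solve(Kmm, rhs)
    alpha = x[pos_i, 0]              # (K_mm^{-1})_{ii}
    beta = x[pos_i, 1]               # (K_mm^{-1} k0)_i
    gamma = float(k0 @ x[:, 1])      # k0^T K_mm^{-1} k0
    s2 = 1.0 / (B[j, j] * alpha)
    mu = -(B[i, j] + B[j, j] * beta) * s2
    log_factor = 0.5 * np.log(2.0 * np.pi * s2) + 0.5 * mu * mu / s2
    return log_factor, mu, s2, alpha, beta, gamma


def _run_chain(
    Sigma: ScatterMatrix,
    theta: EdgePrior,
    prior: PrecisionPrior,
    cfg: McmcConfig,
    rng: np.random.Generator,
    chain_id: int,
    streamline_terms: _StreamlineTerms | None,
) -> PosteriorSamples:
    p = Sigma.p
    delta, D = prior.delta, prior.scale_for(p)
    prior_scale = _ScaleInfo(D, delta)
    post_scale = _ScaleInfo(D + Sigma.sigma, delta + Sigma.n)
    B_post = post_scale.B
    full_tril = np.tril_indices(p, k=-1)

    free_pairs = theta.free_pairs()
    adj = np.zeros((p, p), dtype=np.int8)
    for i, j in theta.hard_edges():  # prior probability 1: always present
        adj[i, j] = adj[j, i] = 1

    caches: dict[bytes, _GraphCache] = {}

    def cache_for(adjacency: np.ndarray) -> _GraphCache:
        key = adjacency.tobytes()
        c = caches.get(key)
        if c is None:
            c = _GraphCache(adjacency)
            caches[key] = c
        return c

    cache = cache_for(adj)
    K = _direct_draw(cache, post_scale, cfg.gibbs_sweeps, rng, full_tril)

    burn_in = cfg.resolved_burn_in()
    keep_at = np.unique(np.linspace(burn_in, cfg.n_iterations - 1, cfg.thin_to).astype(int))
    keep_set = set(keep_at.tolist())

    graphs: list[Graph] = []
    precisions: list[PrecisionMatrix] = []
    n_accept = 0
    n_proposed = 0

    for it in range(cfg.n_iterations):
        if free_pairs:
            i, j = free_pairs[rng.integers(len(free_pairs))]
            adding = adj[i, j] == 0
            adj_prop = adj.copy()
            adj_prop[i, j] = adj_prop[j, i] = 1 if adding else 0
            cache_prop = cache_for(adj_prop)

            # auxiliary prior draw under the *proposed* graph: the exchange
            # construction that cancels the intractable prior constants
            K_aux = _direct_draw(cache_prop, prior_scale, cfg.gibbs_sweeps, rng, full_tril)
            log_post_factor, mu, s2, alpha, beta, gamma = _edge_conditional(K, B_post, i, j)
            log_prior_factor = _edge_conditional(K_aux, D, i, j)[0]

            t = theta.theta[i, j]
            log_odds = np.log(t) - np.log1p(-t)
            if adding:
                log_r = log_odds + log_post_factor - log_prior_factor
            else:
                log_r = -log_odds - log_post_factor + log_prior_factor
            if streamline_terms is not None:
                log_r += streamline_terms.flip_delta(adj, i, j)

            n_proposed += 1
            if np.log(rng.random()) < log_r:
                # dimension-matched K update: hold the Schur complement of
                # row/column j fixed, draw (or zero) the edge element from its
                # conditional, and restore k_jj accordingly
                k_cur = K[i, j]
                s_schur = K[j, j] - (alpha * k_cur**2 + 2.0 * beta * k_cur + gamma)
                k_new = rng.normal(mu, np.sqrt(s2)) if adding else 0.0
                K[i, j] = K[j, i] = k_new
                K[j, j] = s_schur + alpha * k_new**2 + 2.0 * beta * k_new + gamma
                adj = adj_prop
                cache = cache_prop
                n_accept += 1

        # conjugate refresh of K given G via exact clique-block Gibbs sweeps
        _gibbs_sweeps_fast(K, cache, post_scale, max(cfg.gibbs_sweeps, 1), rng)

        if it in keep_set:
            g = Graph(adj.copy())
            graphs.append(g)
            K_out = K.copy()
            K_out[cache.nonedge] = 0.0
            precisions.append(PrecisionMatrix(0.5 * (K_out + K_out.T), g))

    meta = {
        "seed": cfg.seed,
        "chain_id": np.full(len(graphs), chain_id),
        "burn_in": burn_in,
        "n_iterations": cfg.n_iterations,
        "thin_to": cfg.thin_to,
        "acceptance_rate": n_accept / max(n_proposed, 1),
        "delta": delta,
        "n": Sigma.n,
    }
    return PosteriorSamples(graphs, precisions, meta)


def _combine(chains: list[PosteriorSamples]) -> PosteriorSamples:
    graphs = [g for c in chains for g in c.graphs]
    precisions = [k for c in chains for k in c.precisions]
    meta = dict(chains[0].meta)
    meta["chain_id"] = np.concatenate([np.asarray(c.meta["chain_id"]) for c in chains])
    meta["acceptance_rate"] = float(
        np.mean([c.meta["acceptance_rate"] for c in chains])
    )
    return PosteriorSamples(graphs, precisions, meta)


def _sample(
    Sigma: ScatterMatrix,
    theta: EdgePrior,
    prior: PrecisionPrior,
    cfg: McmcConfig,
    streamline_terms: _StreamlineTerms | None,
) -> PosteriorSamples:
    cfg.validate()
    if theta.p != Sigma.p:
        raise ValueError("edge prior and data dimensions do not match")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [
        _run_chain(Sigma, theta, prior, cfg, np.random.default_rng(s), cid, streamline_terms)
        for cid, s in enumerate(seeds)
    ]
    return _combine(chains)


def sample_joint_posterior(
    X: TimeSeriesData,
    theta: EdgePrior,
    prior: PrecisionPrior = PrecisionPrior(),
    cfg: McmcConfig = McmcConfig(),
) -> PosteriorSamples:
    """Thinned draws approximating ``P(G, K | X)``.

    ``theta`` entries of 0/1 are honored as hard constraints; the retained
    sample contains ``thin_to`` draws per chain, pooled across chains (use
    ``by_chain()`` to split them again for diagnostics).
    """
    return _sample(scatter_matrix(X), theta, prior, cfg, None)


def sample_fused_posterior(
    X: TimeSeriesData,
    S: StreamlineCounts,
    theta: EdgePrior,
    prior: PrecisionPrior = PrecisionPrior(),
    alpha: float = 1.0,
    beta: float = 0.5,
    cfg: McmcConfig = McmcConfig(),
) -> PosteriorSamples:
    """Draws from the fused posterior ``P(G, K | X, S)`` combining the Gaussian
    time-series likelihood with the Dirichlet-multinomial streamline model."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if tuple(S.region_labels) != tuple(X.region_labels):
        raise ValueError("region labels of the time series and streamline counts differ")
    return _sample(scatter_matrix(X), theta, prior, cfg, _StreamlineTerms(S, alpha, beta))


def sample_prior_only(
    p: int,
    theta: EdgePrior,
    prior: PrecisionPrior = PrecisionPrior(),
    cfg: McmcConfig = McmcConfig(),
) -> PosteriorSamples:
    """Run the sampler with no data (scatter 0, n = 0); the stationary law of
    the graph marginal is then the Bernoulli edge prior itself.  Used as a
    detailed-balance smoke test."""
    Sigma = ScatterMatrix(np.zeros((p, p)), 0)
    return _sample(Sigma, theta, prior, cfg, None)


def convergence_report(chains: list[PosteriorSamples], threshold: float = 0.05) -> ConvergenceReport:
    """Maximum absolute cross-chain difference in per-edge inclusion
    probabilities, with a pass/fail flag at ``threshold``."""
    if len(chains) < 2:
        raise ValueError("convergence assessment requires at least 2 chains")
    probs = np.stack([c.edge_probabilities() for c in chains])
    per_edge = probs.max(axis=0) - probs.min(axis=0)
    np.fill_diagonal(per_edge, 0.0)
    max_disc = float(per_edge.max())
    return ConvergenceReport(max_disc, per_edge, threshold, max_disc <= threshold)
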