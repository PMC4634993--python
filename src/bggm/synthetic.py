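"""Synthetic fixtures: ground-truth graphs, graph-constrained precisions,
Gaussian time series, and Dirichlet-multinomial streamline counts.

The generator mirrors the package's own generative model: a random graph, a
G-Wishart precision restricted to it, zero-mean Gaussian observations with
covariance ``K^{-1}``, and per-seed-region streamline counts whose Dirichlet
concentrations are ``alpha`` on edges and ``beta`` on non-edges.  A
``mismatch_rate`` flips the edge indicator for a fraction of pairs inside the
streamline generator only, modelling modalities that contradict each other
while the Gaussian data stay faithful to the true graph.

Because draws from a vague G-Wishart can place partial correlations near zero
on true edges — which would make recovery experiments unidentifiable rather
than hard — ``sample_ground_truth`` redraws (bounded retries) until every true
edge carries a partial correlation of at least ``min_abs_partial``.

All generators take explicit seeds; no global RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    Graph,
    PartialCorrelationMatrix,
    PrecisionMatrix,
    TimeSeriesData,
    cholesky_pd,
    precision_to_partial,
)
from .evaluation import GroundTruth
from .fusion import StreamlineCounts
from .gwishart import _sample_gwishart_raw

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "random_graph",
    "sample_ground_truth",
    "simulate_timeseries",
    "simulate_streamlines",
    "make_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A full simulation scenario; defaults give the standard recovery setting
    (10 regions, 2000 time points, 30% edge density, |r| >= 0.25 on edges,
    vague G-Wishart generator, (alpha, beta) = (1, 0.5), 1000 streamlines per
    seed region, no modality mismatch)."""

    p: int = 10
    n: int = 2000
    density: float = 0.3
    delta: float = 3.0
    D: np.ndarray | None = None
    min_abs_partial: float = 0.25
    alpha: float = 1.0
    beta: float = 0.5
    row_totals: int = 1000
    mismatch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise ValueError("mismatch_rate must lie in [0, 1]")
        if self.p < 2 or self.n < 1 or self.row_totals < 0:
            raise ValueError("need p >= 2, n >= 1, row_totals >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")

    def scale_for(self) -> np.ndarray:
        if self.D is None:
            return np.eye(self.p)
        return np.asarray(self.D, dtype=float)


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything a recovery experiment needs, generated from one seed."""

    graph: Graph
    precision: PrecisionMatrix
    partials: PartialCorrelationMatrix
    truth: GroundTruth
    timeseries: TimeSeriesData
    streamlines: StreamlineCounts
    config: ScenarioConfig


def random_graph(p: int, density: float, seed: int | np.random.Generator) -> Graph:
    """Erdős–Rényi graph: each pair included independently with the given
    density."""
    if p < 2:
        raise ValueError("need p >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    adj = np.zeros((p, p), dtype=np.int8)
    adj[iu] = rng.random(len(iu[0])) < density
    return Graph(adj + adj.T)


def sample_ground_truth(
    G: Graph,
    delta: float = 3.0,
    D: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    min_abs_partial: float = 0.25,
    max_retries: int = 1000,
) -> tuple[PrecisionMatrix, PartialCorrelationMatrix, GroundTruth]:
    """Ground-truth precision from W_G(delta, D), rejection-sampled until every
    true edge has |partial correlation| >= ``min_abs_partial``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = np.eye(G.p) if D is None else np.asarray(D, dtype=float)
    edges = G.edges()
    for _ in range(max_retries):
        raw = _sample_gwishart_raw(G.adjacency, delta, scale, 1, rng)[0]
        K = PrecisionMatrix(raw, G)
        R = precision_to_partial(K)
        if all(abs(R.values[i, j]) >= min_abs_partial for i, j in edges):
            truth = GroundTruth(R, G.adjacency.copy())
            return K, R, truth
    raise RuntimeError(
        f"no G-Wishart draw satisfied |partial| >= {min_abs_partial} on all "
        f"{len(edges)} edges within {max_retries} retries; lower the threshold "
        "or the graph density"
    )


def simulate_timeseries(K: PrecisionMatrix, n: int,
                        seed: int | np.random.Generator = 0) -> TimeSeriesData:
    """n i.i.d. zero-mean Gaussian rows with covariance ``K^{-1}``."""
    if n < 1:
        raise ValueError("need n >= 1 observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = cholesky_pd(K.values, "precision")
    z = rng.standard_normal((n, K.p))
    # x = L^{-T} z has covariance (L L^T)^{-1} = K^{-1}
    x = np.linalg.solve(L.T, z.T).T
    return TimeSeriesData(x)


def simulate_streamlines(
    G: Graph,
    alpha: float = 1.0,
    beta: float = 0.5,
    row_totals: int | np.ndarray = 1000,
    mismatch_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> StreamlineCounts:
    """Per-seed-region Dirichlet-multinomial streamline counts.

    Row j sums to its total; concentrations are ``alpha`` on edges and ``beta``
    on non-edges after flipping the edge indicator of a ``mismatch_rate``
    fraction of pairs (rounded up), selected uniformly at random.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if not 0.0 <= mismatch_rate <= 1.0:
        raise ValueError("mismatch_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = G.p
    totals = np.broadcast_to(np.asarray(row_totals, dtype=np.int64), (p,)).copy()
    if np.any(totals < 0):
        raise ValueError("row totals must be >= 0")
    adj = G.adjacency.copy()
    iu = np.triu_indices(p, k=1)
    n_pairs = len(iu[0])
    n_flip = int(np.ceil(mismatch_rate * n_pairs)) if mismatch_rate > 0 else 0
    if n_flip:
        chosen = rng.choice(n_pairs, size=n_flip, replace=False)
        rows, cols = iu[0][chosen], iu[1][chosen]
        adj[rows, cols] = 1 - adj[rows, cols]
        adj[cols, rows] = adj[rows, cols]
    counts = np.zeros((p, p), dtype=np.int64)
    for j in range(p):
        if totals[j] == 0:
            continue
        others = np.flatnonzero(np.arange(p) != j)
        conc = np.where(adj[others, j] == 1, alpha, beta)
        probs = rng.dirichlet(conc)
        counts[j, others] = rng.multinomial(totals[j], probs)
    return StreamlineCounts(counts)


def make_scenario(config: ScenarioConfig = ScenarioConfig()) -> ScenarioBundle:
    """Generate the full fixture bundle for one scenario seed.

    Rejection runs over the joint (graph, precision) draw: a graph whose
    retry budget is exhausted — typical when a hub node's high degree makes
    simultaneously large partial correlations improbable — is redrawn.
    """
    rng = np.random.default_rng(config.seed)
    for attempt in range(50):
        G = random_graph(config.p, config.density, rng)
        try:
            K, R, truth = sample_ground_truth(
                G, config.delta, config.scale_for(), rng, config.min_abs_partial,
                max_retries=400,
            )
            break
        except RuntimeError:
            continue
    else:
        raise RuntimeError(
            f"no (graph, precision) pair satisfied |partial| >= "
            f"{config.min_abs_partial} at density {config.density}"
        )
    X = simulate_timeseries(K, config.n, rng)
    S = simulate_streamlines(
        G, config.alpha, config.beta, config.row_totals, config.mismatch_rate, rng
    )
    return ScenarioBundle(G, K, R, truth, X, S, config)
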