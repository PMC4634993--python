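"""Dirichlet-multinomial likelihood linking tractography streamline counts to
the conditional-independence graph.

Row j of the count matrix holds the probabilistic streamline counts seeded in
region j towards every other region.  Given the graph, row j is modelled as a
Dirichlet-multinomial draw whose concentration for target i is ``alpha`` when
the (symmetric) edge i-j is present and ``beta`` when it is absent; with the
default (alpha, beta) = (1, 0.5), high counts are more probable across existing
connections while tractography noise on absent ones is still tolerated.

The multinomial coefficient is included, so each row's pmf is a true
probability over count vectors with a fixed total; it is constant in G and
therefore does not affect inference.  Rows are conditionally independent given
the graph, and a zero row total contributes zero to the log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import dirichlet_multinomial

from .data import Graph

__all__ = ["StreamlineCounts", "dirmult_log_likelihood"]


@dataclass(frozen=True)
class StreamlineCounts:
    """p x p nonnegative integer matrix of streamline counts, zero diagonal.

    Rows need not be symmetric: seeding in region j and seeding in region i are
    separate tractography runs.
    """

    counts: np.ndarray
    region_labels: tuple[str, ...] = ()

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("streamline counts must form a square matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = np.asarray(counts, dtype=np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("streamline counts must be integers")
            counts = as_int
        bad = np.argwhere(counts < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"negative streamline count at row {i}, column {j}")
        if np.any(np.diag(counts) != 0):
            raise ValueError("streamline count diagonal must be zero")
        labels = tuple(self.region_labels) or tuple(
            f"region_{i}" for i in range(counts.shape[0])
        )
        if len(labels) != counts.shape[0]:
            raise ValueError("label count does not match matrix size")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "region_labels", labels)

    @property
    def p(self) -> int:
        return self.counts.shape[0]


def _row_log_likelihood(row_counts: np.ndarray, conc: np.ndarray) -> float:
    total = int(row_counts.sum())
    if total == 0:
        return 0.0
    return float(dirichlet_multinomial.logpmf(row_counts, conc, total))


def dirmult_log_likelihood(S: StreamlineCounts, G: Graph,
                           alpha: float = 1.0, beta: float = 0.5) -> float:
    """Log probability of the streamline counts given the graph.

    For each seed region j the targets i != j receive concentration
    ``alpha * g_ij + beta * (1 - g_ij)``; the per-row Dirichlet-multinomial
    log-pmfs (multinomial coefficient included) are summed over rows.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if S.p != G.p:
        raise ValueError("streamline matrix and graph dimensions do not match")
    adj = G.adjacency
    total = 0.0
    p = S.p
    for j in range(p):
        others = np.arange(p) != j
        conc = np.where(adj[others, j] == 1, float(alpha), float(beta))
        total += _row_log_likelihood(S.counts[j, others], conc)
    return total


def dirmult_row_terms(S: StreamlineCounts, G: Graph, alpha: float, beta: float) -> np.ndarray:
    """Per-row log-likelihood terms; their sum equals ``dirmult_log_likelihood``.

    Exposed for samplers that flip a single edge: only the two incident rows
    change, so the difference in log-likelihood can be computed from two terms.
    """
    adj = G.adjacency
    p = S.p
    out = np.empty(p)
    for j in range(p):
        others = np.arange(p) != j
        conc = np.where(adj[others, j] == 1, float(alpha), float(beta))
        out[j] = _row_log_likelihood(S.counts[j, others], conc)
    return out
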