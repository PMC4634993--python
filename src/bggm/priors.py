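"""Prior distributions over conditional-independence graphs.

Two priors are provided: a (possibly edge-specific) independent Bernoulli prior
with inclusion probabilities ``theta_ij``, and a homotopy-informed prior for
bilateral brain parcellations that fixes homotopic interhemispheric edges to
probability 1, forbids all other interhemispheric edges, and stays agnostic
(theta = 0.5 by default) within a hemisphere.

Entries of 0 or 1 are hard constraints: downstream samplers never propose
flipping such edges, which both avoids -inf arithmetic and implements the
prior's intent of excluding (or requiring) specific connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Graph

__all__ = ["EdgePrior", "RegionAnnotation", "graph_log_prior", "homotopy_prior"]


@dataclass(frozen=True)
class EdgePrior:
    """Symmetric matrix of prior edge-inclusion probabilities in [0, 1].

    Only the upper triangle is authoritative; the matrix is symmetrized on
    construction and the diagonal is ignored.
    """

    theta: np.ndarray

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValueError("theta must be a square matrix")
        if np.any((theta < 0) | (theta > 1)) or not np.all(np.isfinite(theta)):
            raise ValueError("edge-prior probabilities must lie in [0, 1]")
        iu = np.triu_indices(theta.shape[0], k=1)
        sym = np.zeros_like(theta)
        sym[iu] = theta[iu]
        sym = sym + sym.T
        np.fill_diagonal(sym, 0.0)
        object.__setattr__(self, "theta", sym)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def flat(cls, p: int, theta: float = 0.5) -> "EdgePrior":
        return cls(np.full((p, p), float(theta)))

    def free_pairs(self) -> list[tuple[int, int]]:
        """Pairs whose prior probability is strictly inside (0, 1)."""
        iu = np.triu_indices(self.p, k=1)
        free = (self.theta[iu] > 0.0) & (self.theta[iu] < 1.0)
        return list(zip(iu[0][free].tolist(), iu[1][free].tolist()))

    def hard_edges(self) -> list[tuple[int, int]]:
        """Pairs with prior probability exactly 1 (forced present)."""
        iu = np.triu_indices(self.p, k=1)
        hard = self.theta[iu] == 1.0
        return list(zip(iu[0][hard].tolist(), iu[1][hard].tolist()))


@dataclass(frozen=True)
class RegionAnnotation:
    """Hemisphere labels plus a partial homotopy pairing between hemispheres."""

    hemisphere: tuple[str, ...]
    homotope_of: dict[int, int]

    def __post_init__(self):
        hemis = tuple(str(h).lower() for h in self.hemisphere)
        if any(h not in ("left", "right") for h in hemis):
            raise ValueError("hemisphere labels must be 'left' or 'right'")
        pairs = dict(self.homotope_of)
        for i, j in pairs.items():
            if pairs.get(j) != i:
                raise ValueError(f"homotopy pairing is not mutual for regions {i} and {j}")
            if hemis[i] == hemis[j]:
                raise ValueError(
                    f"regions {i} and {j} are in the same hemisphere and cannot be homotopes"
                )
        object.__setattr__(self, "hemisphere", hemis)
        object.__setattr__(self, "homotope_of", pairs)

    @property
    def p(self) -> int:
        return len(self.hemisphere)


def graph_log_prior(G: Graph, theta: EdgePrior) -> float:
    """Log prior probability of G under independent Bernoulli edges.

    Returns ``sum_{i<j} g_ij log(theta_ij) + (1 - g_ij) log(1 - theta_ij)``;
    -inf if and only if some hard constraint (theta in {0, 1}) is violated.
    """
    if G.p != theta.p:
        raise ValueError("graph and prior dimensions do not match")
    iu = np.triu_indices(G.p, k=1)
    g = G.adjacency[iu].astype(float)
    t = theta.theta[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(g == 1, np.log(t), np.log1p(-t))
    if np.any(np.isneginf(terms)):
        return float("-inf")
    return float(terms.sum())


def homotopy_prior(annotation: RegionAnnotation, within_theta: float = 0.5) -> EdgePrior:
    """Edge prior encoding direct homotopic connections and no other
    interhemispheric connectivity.

    theta_ij is ``within_theta`` for same-hemisphere pairs, 1 for homotopic
    pairs, and 0 for every other interhemispheric pair.
    """
    if not 0.0 <= within_theta <= 1.0:
        raise ValueError("within_theta must lie in [0, 1]")
    p = annotation.p
    hemis = np.array([0 if h == "left" else 1 for h in annotation.hemisphere])
    theta = np.where(hemis[:, None] == hemis[None, :], float(within_theta), 0.0)
    for i, j in annotation.homotope_of.items():
        theta[i, j] = theta[j, i] = 1.0
    np.fill_diagonal(theta, 0.0)
    return EdgePrior(theta)
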