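"""Core domain types for Gaussian graphical modelling of multivariate time series.

The central objects are a region-by-region conditional-independence graph
``Graph``, a positive-definite precision matrix ``PrecisionMatrix`` whose
off-graph entries are exactly zero, and the partial-correlation matrix obtained
from it by ``precision_to_partial``.  Observed data live in ``TimeSeriesData``
(rows are time points, columns are regions) and enter the likelihood only
through the unnormalized scatter matrix ``Sigma = X.T @ X`` together with the
sample count ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesData",
    "ScatterMatrix",
    "Graph",
    "PrecisionMatrix",
    "PartialCorrelationMatrix",
    "standardize_timeseries",
    "scatter_matrix",
    "gaussian_log_likelihood",
    "precision_to_partial",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically unusable."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_symmetric(a: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (a + a.T)


def cholesky_pd(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Cholesky factor of ``a``; raises if not positive definite (no clipping)."""
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


@dataclass(frozen=True)
class TimeSeriesData:
    """An n x p matrix of observations: rows are time points, columns regions."""

    values: np.ndarray
    region_labels: tuple[str, ...] = ()
    standardized: bool = False

    def __post_init__(self):
        values = _as_float_array(self.values, "values")
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D array")
        n, p = values.shape
        if n < 1 or p < 2:
            raise ValueError(f"need n >= 1 observations and p >= 2 regions, got {n} x {p}")
        labels = tuple(self.region_labels) or tuple(f"region_{i}" for i in range(p))
        if len(labels) != p:
            raise ValueError(f"{len(labels)} labels for {p} columns")
        if self.standardized:
            if not (
                np.allclose(values.mean(axis=0), 0.0, atol=1e-8)
                and np.allclose(values.var(axis=0), 1.0, atol=1e-8)
            ):
                raise ValueError("standardized flag set but columns are not (mean 0, var 1)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, standardized: bool = False) -> "TimeSeriesData":
        return cls(frame.to_numpy(dtype=float), tuple(str(c) for c in frame.columns), standardized)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.region_labels))


@dataclass(frozen=True)
class ScatterMatrix:
    """Unnormalized scatter ``Sigma = X.T @ X`` together with the sample count n.

    ``Sigma`` is kept unnormalized (never divided by n): the conjugate update of
    the G-Wishart prior adds the scatter to the prior scale matrix directly.
    """

    sigma: np.ndarray
    n: int

    def __post_init__(self):
        sigma = _check_symmetric(_as_float_array(self.sigma, "sigma"), "sigma")
        eigmin = float(np.linalg.eigvalsh(sigma).min())
        if eigmin < -1e-8 * max(1.0, float(np.abs(sigma).max())):
            raise ValueError("scatter matrix must be positive semi-definite")
        if self.n < 0:
            raise ValueError("sample count must be >= 0")
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "n", int(self.n))

    @property
    def p(self) -> int:
        return self.sigma.shape[0]


@dataclass(frozen=True)
class Graph:
    """Symmetric binary adjacency over p nodes; absent edges are conditional
    independencies."""

    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        adj = adj.astype(np.int8)
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", adj)

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.p, k=1)
        mask = self.adjacency[iu] == 1
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))

    def to_bitstring(self) -> str:
        iu = np.triu_indices(self.p, k=1)
        return "".join("1" if g else "0" for g in self.adjacency[iu])

    @classmethod
    def from_bitstring(cls, bits: str, p: int) -> "Graph":
        iu = np.triu_indices(p, k=1)
        if len(bits) != iu[0].size:
            raise ValueError(f"bitstring length {len(bits)} does not match p={p}")
        adj = np.zeros((p, p), dtype=np.int8)
        adj[iu] = np.array([int(b) for b in bits], dtype=np.int8)
        return cls(adj + adj.T)

    @classmethod
    def empty(cls, p: int) -> "Graph":
        return cls(np.zeros((p, p), dtype=np.int8))

    @classmethod
    def complete(cls, p: int) -> "Graph":
        return cls(np.ones((p, p), dtype=np.int8) - np.eye(p, dtype=np.int8))


@dataclass(frozen=True)
class PrecisionMatrix:
    """Positive-definite precision (inverse covariance) matrix, optionally tied
    to a graph whose non-edges must be exact zeros."""

    values: np.ndarray
    graph: Graph | None = None

    def __post_init__(self):
        values = _check_symmetric(_as_float_array(self.values, "precision"), "precision")
        cholesky_pd(values, "precision")
        if self.graph is not None:
            if self.graph.p != values.shape[0]:
                raise ValueError("graph size does not match precision matrix")
            off = (self.graph.adjacency == 0) & ~np.eye(self.graph.p, dtype=bool)
            if np.any(values[off] != 0.0):
                raise ValueError("precision has nonzero entries off the graph's edge set")
        object.__setattr__(self, "values", values)

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PartialCorrelationMatrix:
    """Symmetric matrix of partial correlations with unit diagonal."""

    values: np.ndarray

    def __post_init__(self):
        values = _check_symmetric(_as_float_array(self.values, "partial correlations"),
                                  "partial correlations")
        if not np.allclose(np.diag(values), 1.0, atol=1e-10):
            raise ValueError("diagonal of a partial-correlation matrix must be 1")
        np.fill_diagonal(values, 1.0)
        off = values[~np.eye(values.shape[0], dtype=bool)]
        if off.size and (off.min() < -1.0 or off.max() > 1.0):
            raise ValueError("off-diagonal partial correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", values)

    @property
    def p(self) -> int:
        return self.values.shape[0]


def standardize_timeseries(X: TimeSeriesData) -> TimeSeriesData:
    """Rescale each column to mean 0 and variance 1 (population, 1/n denominator).

    The 1/n convention makes "unit variance" exact for the scatter-based
    likelihood: after standardization ``diag(X.T X) == n``.
    """
    values = X.values
    mu = values.mean(axis=0)
    sd = values.std(axis=0)  # population (1/n) standard deviation
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = ", ".join(X.region_labels[i] for i in bad)
        raise DegenerateInputError(f"constant column(s) cannot be standardized: {names}")
    return replace(X, values=(values - mu) / sd, standardized=True)


def scatter_matrix(X: TimeSeriesData) -> ScatterMatrix:
    """Unnormalized scatter ``Sigma = X.T @ X`` and the number of rows n."""
    return ScatterMatrix(X.values.T @ X.values, X.n)


def gaussian_log_likelihood(K: PrecisionMatrix, Sigma: ScatterMatrix) -> float:
    """Full log density of n i.i.d. zero-mean Gaussian rows with precision K.

    Returns ``(n/2) log|K| - (1/2) <K, Sigma> - (n p / 2) log(2 pi)``, i.e. the
    normalized density (constant included) so values are comparable across
    graphs and models.
    """
    if K.p != Sigma.p:
        raise ValueError(f"dimension mismatch: K is {K.p} x {K.p}, Sigma is {Sigma.p} x {Sigma.p}")
    chol = cholesky_pd(K.values, "precision")
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    n, p = Sigma.n, Sigma.p
    return 0.5 * n * logdet - 0.5 * float(np.sum(K.values * Sigma.sigma)) - 0.5 * n * p * LOG_2PI


def precision_to_partial(K: PrecisionMatrix) -> PartialCorrelationMatrix:
    """Partial correlations ``r_ij = -k_ij / sqrt(k_ii k_jj)``, with unit diagonal.

    Zeros of K map to exact zeros of R, so the conditional-independence pattern
    is preserved by the transform.
    """
    k = K.values
    d = np.diag(k)
    if np.any(d <= 0):
        raise ValueError("precision matrix has a nonpositive diagonal element")
    scale = np.sqrt(d)
    r = -k / np.outer(scale, scale)
    np.fill_diagonal(r, 1.0)
    return PartialCorrelationMatrix(r)
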