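"""Point-estimate comparators: maximum-likelihood and graphical-LASSO
precision matrices.

Both operate on the unnormalized scatter ``Sigma = X^T X``, so the LASSO
penalty ``lambda`` is interpreted on that scale; the benchmark values
``lambda in {5, 100}`` used in the simulation literature are exposed as
``LAMBDA_PRESETS``.

The LASSO solver maximizes ``log|K| - <Sigma, K> - lambda ||K||_1`` (penalty on
the off-diagonal by default) by proximal-gradient ascent with monotone
backtracking: each iteration takes a gradient step on the smooth part
(gradient ``K^{-1} - Sigma``), soft-thresholds the penalized entries — which
produces exact zeros — and halves the step until the objective does not
decrease and the iterate stays positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PrecisionMatrix, ScatterMatrix

__all__ = ["LassoConfig", "mle_precision", "glasso_precision", "glasso_objective",
           "LAMBDA_PRESETS"]

LAMBDA_PRESETS = (5.0, 100.0)


@dataclass(frozen=True)
class LassoConfig:
    """Penalty and solver controls for the graphical LASSO.

    ``tolerance`` bounds the maximum violation of the stationarity (KKT)
    conditions on the normalized scatter scale — a direct measure of solution
    quality, unlike an iterate-change criterion.
    """

    lam: float
    max_iterations: int = 100_000
    tolerance: float = 1e-6
    penalize_diagonal: bool = False

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("penalty lambda must be >= 0")
        if self.max_iterations < 1 or self.tolerance <= 0:
            raise ValueError("max_iterations must be >= 1 and tolerance > 0")


def mle_precision(Sigma: ScatterMatrix) -> PrecisionMatrix:
    """Maximum-likelihood precision ``Sigma^{-1}`` (Sigma = X^T X).

    Fails with an informative error when the scatter is singular, which is
    guaranteed whenever n < p and common for rank-deficient data.
    """
    s = Sigma.sigma
    eigs = np.linalg.eigvalsh(s)
    if eigs.min() <= 1e-10 * max(eigs.max(), 1.0):
        raise ValueError(
            "scatter matrix is singular or indefinite: no unique maximum-likelihood "
            "precision exists (typically n < p or rank-deficient data); consider the "
            "graphical LASSO or the Bayesian model instead"
        )
    k = np.linalg.inv(s)
    return PrecisionMatrix(0.5 * (k + k.T))


def glasso_objective(K: np.ndarray, sigma: np.ndarray, lam: float,
                     penalize_diagonal: bool = False) -> float:
    """The penalized log-likelihood ``log|K| - <Sigma, K> - lam * ||K||_1``."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    penalty = np.abs(K).sum() if penalize_diagonal else np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return float(logdet - np.sum(sigma * K) - lam * penalty)


def _soft_threshold(K: np.ndarray, t: float, penalize_diagonal: bool) -> np.ndarray:
    diag = np.diag(K).copy()
    out = np.sign(K) * np.maximum(np.abs(K) - t, 0.0)
    if not penalize_diagonal:
        np.fill_diagonal(out, diag)
    return 0.5 * (out + out.T)


def _is_pd(K: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(K)
        return True
    except np.linalg.LinAlgError:
        return False


def glasso_precision(Sigma: ScatterMatrix, cfg: LassoConfig,
                     callback=None) -> PrecisionMatrix:
    """Graphical-LASSO precision estimate for the given penalty.

    ``callback(iteration, objective)``, if given, is invoked once per accepted
    iterate (used by tests to check the objective never decreases).
    Non-convergence raises with the final duality gap.
    """
    p = Sigma.p
    # solve on a normalized scale (scatter divided by its mean diagonal) so the
    # iterates are O(1) and the stopping tolerance is effectively relative;
    # substituting K = K'/c shows the two problems share their maximizer
    c = max(float(np.diag(Sigma.sigma).mean()), 1e-12)
    sigma = Sigma.sigma / c
    lam = float(cfg.lam) / c
    K = np.linalg.inv(sigma + lam * np.eye(p))
    K = 0.5 * (K + K.T)
    obj = glasso_objective(K, sigma, lam, cfg.penalize_diagonal)

    def smooth(k):  # -(concave smooth part); minimized by the gradient steps
        sign, logdet = np.linalg.slogdet(k)
        return np.inf if sign <= 0 else float(np.sum(sigma * k) - logdet)

    g_cur = smooth(K)
    base_step = 1.0 / max(float(np.linalg.norm(sigma, 2)), 1e-12)
    step = base_step

    def kkt_residual(k):
        """Max violation of the stationarity conditions (normalized scale)."""
        w = np.linalg.inv(k) - sigma
        off = ~np.eye(p, dtype=bool)
        resid = float(np.abs(np.diag(w)).max()) if not cfg.penalize_diagonal else 0.0
        active = off & (k != 0)
        inactive = off & (k == 0)
        if active.any():
            resid = max(resid, float(np.abs(w[active] - lam * np.sign(k[active])).max()))
        if inactive.any():
            resid = max(resid, float(np.maximum(np.abs(w[inactive]) - lam, 0.0).max()))
        return resid

    for it in range(cfg.max_iterations):
        grad = sigma - np.linalg.inv(K)  # gradient of the smooth part
        grad = 0.5 * (grad + grad.T)
        # persistent shrink-only step avoids limit cycles; reset it
        # periodically so an early conservative shrink cannot stall progress
        t = base_step if it % 50 == 0 else step
        while True:
            K_new = _soft_threshold(K - t * grad, t * lam, cfg.penalize_diagonal)
            if _is_pd(K_new):
                d = K_new - K
                g_new = smooth(K_new)
                # descent-lemma backtracking guarantees a monotone objective
                if g_new <= g_cur + float(np.sum(grad * d)) + np.sum(d * d) / (2 * t) + 1e-14:
                    break
            t *= 0.5
            if t < 1e-18:
                raise RuntimeError("graphical LASSO line search failed")
        K, g_cur, step = K_new, g_new, t
        obj = glasso_objective(K, sigma, lam, cfg.penalize_diagonal)
        if callback is not None:
            callback(it, obj)
        if kkt_residual(K) < cfg.tolerance:
            return PrecisionMatrix(K / c)
    pen = np.abs(K).sum() if cfg.penalize_diagonal else np.abs(K).sum() - np.abs(np.diag(K)).sum()
    gap = float(np.sum(sigma * K) + lam * pen - p)
    raise RuntimeError(
        f"graphical LASSO did not converge in {cfg.max_iterations} iterations "
        f"(duality gap {gap:.3e}); increase max_iterations or loosen the tolerance"
    )
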