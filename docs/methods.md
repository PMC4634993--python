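# Methods

## The model

Let `X` be an n x p matrix of region time series, modelled as n independent
zero-mean Gaussian draws with precision matrix `K`; the likelihood depends on
the data only through the unnormalized scatter `Sigma = X'X` and n. Empirical
series are standardized column-wise to mean 0 and variance 1 before inference
(population 1/n denominator, so `diag(Sigma) = n` exactly; a flag switches to
1/(n-1) if a caller insists). We never divide the scatter by n: the conjugate
update below adds it to the prior scale directly, and the LASSO penalty is
interpreted on the same scale so that the conventional benchmark penalties
5 and 100 are meaningful.

The joint posterior over the conditional-independence graph `G` and `K` is

    P(G, K | X) ∝ P(X | K) · P(K | G) · P(G),

with `P(K | G) = W_G(delta, D)`, the G-Wishart law with kernel
`|K|^((delta-2)/2) exp(-<K, D>/2)` restricted to the cone `P_G` of SPD
matrices with zeros at non-edges, and `P(G)` an independent Bernoulli edge
prior `theta_ij`. Conjugacy gives `K | G, X ~ W_G(delta + n, D + Sigma)`.
Defaults: `delta = 3`, `D = I` (a vague prior — the prior mean of `K` on the
complete graph is `(delta + p - 1) I`), `theta_ij = 0.5` (indifference).
Partial correlations are `r_ij = -k_ij / sqrt(k_ii k_jj)`; the transform is
scale-invariant and maps zeros to zeros, so `P(G, R | X)` carries the same
independence structure.

Two extensions share the graph:

* **Data fusion.** A p x p matrix `S` of probabilistic-tractography streamline
  counts (row j = counts seeded in region j) enters through
  `P(S | G) = prod_j DirMult(s_j | a_j)`, with concentration `alpha` on edges
  and `beta` on non-edges of (the symmetric) `G`; row j uses column j of the
  adjacency, so one edge informs both incident rows. Defaults
  `(alpha, beta) = (1, 0.5)`: high counts are most likely across existing
  connections while tolerating tractography noise. The multinomial coefficient
  is included so each row pmf is a true probability (it is constant in `G` and
  cannot affect inference); empty rows contribute zero.
* **Informative prior.** For bilateral parcellations, the homotopy prior sets
  `theta = 1` for homotopic interhemispheric pairs, `0` for all other
  interhemispheric pairs, and `0.5` within hemispheres. Entries of exactly
  0/1 are treated as hard constraints: the sampler never proposes flipping
  them (edges with prior 1 are inserted at initialization), which avoids
  -inf arithmetic and implements the prior's intent directly.

## Sampling

One iteration updates the graph by a single-edge flip and the precision by
its conjugate conditional.

**Edge flip (double-conditional exchange).** A pair (i, j) is proposed
uniformly over the free pairs. Conditioning on everything but `(k_ij, k_jj)`
and holding the Schur complement `s = k_jj - q(k_ij)` of row/column j fixed,
the target kernel in `k_ij` is Gaussian with variance
`s2 = 1/(b_jj * alpha)` and mean `mu = -(b_ij + b_jj * beta_q) * s2`, where
`q(k) = alpha k^2 + 2 beta_q k + gamma` comes from the remaining entries and
`B` is the relevant scale matrix. Integrating `k_ij` out (edge present)
versus pinning it at zero (edge absent) gives the closed-form conditional
factor `sqrt(2 pi s2) exp(mu^2 / (2 s2))`. The acceptance ratio multiplies

1. the prior odds `theta_e / (1 - theta_e)`,
2. this factor evaluated under the posterior scale `B = D + Sigma` on the
   current chain state, and
3. the reciprocal of the same factor evaluated under the prior scale `B = D`
   on an **auxiliary precision drawn afresh from the prior under the proposed
   graph** — the exchange construction by which the intractable prior
   normalizing constants `Z_G(delta, D)` cancel exactly,
4. plus, in fused mode, the Dirichlet-multinomial ratio of the two incident
   rows (O(1) via precomputed log-Gamma tables).

On acceptance `K` is updated dimension-matched: the edge element is drawn
from (or set to zero by) the same conditional, and `k_jj` is restored so the
Schur complement is preserved — keeping `K` positive definite in the new cone.

**Precision refresh.** The conjugate update `K ~ W_G(delta + n, D + Sigma)`
is applied as exact clique-block Gibbs sweeps: for any complete subset `C`,
the Schur complement of the block given the rest is an unconstrained Wishart
with scale `B_CC`, so resampling it leaves the G-Wishart invariant; sweeping
the maximal cliques covers every free element. Two sweeps per iteration are
the default.

**Direct G-Wishart draws.** Independent draws (the exchange auxiliaries, the
chain initialization, the public sampler, the ground-truth generator) use the
completion-based direct sampler — draw an unconstrained Wishart with df
`delta + p - 1` and scale `D^{-1}` via Bartlett, invert, and project the
implied covariance onto the graph by cyclic block-coordinate completion —
followed by a small number of the same clique-block Gibbs sweeps. The
completion projection alone has exactly the right clique marginals but not
exactly the right joint law (for the fully disconnected graph the target
factorizes over the diagonal while the projection's diagonal entries are
dependent); the correction sweeps remove this residual error. With 2 sweeps
the 3-node enumeration benchmark agrees to 0.0025 in edge probability, with
4 sweeps to 0.0002. Completion runs to a relative tolerance of 1e-9 on the
covariance (up to 5000 sweeps — the tail is driven by ill-conditioned base
draws); non-edges of the returned precision are then set to exactly zero.

**Chains and bookkeeping.** Defaults: 2 chains, 50 000 iterations, 20%
burn-in, uniform thinning to T = 1000 retained draws per chain, explicit seed
(chains are seeded by spawning from it; no global RNG state anywhere in the
package). Graphs are serialized as upper-triangle bitstrings for counting
unique models. Convergence is reported as the maximum absolute cross-chain
difference in per-edge inclusion probabilities, with a pass/fail flag at
0.05 — a pragmatic substitute for a full scale-reduction analysis, adequate
because edge probabilities are the quantities consumed downstream.

## Normalizing constants and the enumeration oracle

The MCMC never evaluates `Z_G`; the constants are needed only by the exact
small-p oracle and its tests. For decomposable (chordal) graphs `Z_G` is the
clique/separator factorization of complete-graph Wishart constants
(`2^{nu m/2} Gamma_m(nu/2) |D_AA|^{-nu/2}`, `nu = delta + m - 1`, separators
from a maximum-weight junction tree). For non-decomposable graphs an unbiased
importance-sampling estimate integrates the kernel over the free upper-Cholesky
elements: free diagonal and edge positions are drawn from a product proposal
matched to `diag(D)`, non-free positions are filled by the zero-constraint
recursion `phi_ij = -(sum_{k<i} phi_ki phi_kj)/phi_ii`, and the
kernel-times-Jacobian over proposal density is averaged, with a delta-method
standard error on the log. For `D = I` the weights reduce to the classical
`exp(-1/2 * sum of squared completion terms)` form. Default 10 000 samples;
the oracle uses 100 000.

The oracle itself enumerates all `2^{p(p-1)/2}` graphs (p <= 4), combines
`log P(X | G) = -(np/2) log 2pi + log Z_G(delta+n, D+Sigma) - log Z_G(delta, D)`
with the Bernoulli prior, normalizes, and returns exact edge probabilities.

## Point-estimate baselines

The MLE is `Sigma^{-1}` (it exists iff the scatter is nonsingular; the error
message points at n < p). The graphical LASSO maximizes
`log|K| - <Sigma, K> - lambda ||K||_1` with the penalty on off-diagonal
entries by default (a flag includes the diagonal). The solver is monotone
proximal-gradient ascent: a gradient step on the smooth part, soft-thresholding
(which yields exact zeros), and descent-lemma backtracking with a persistent
shrink-only step — chosen over dual coordinate descent because it is simple to
verify (the per-iteration objective is exposed to tests, which assert it never
decreases) while agreeing with an independent reference solver to the
tolerances used. The problem is internally rescaled by the mean diagonal of
the scatter so iterates are O(1); convergence is declared when the maximum
violation of the stationarity (KKT) conditions falls below the tolerance
(default 1e-6) — an iterate-change rule proved unreliable, stalling in a
line-search limit cycle within ~1e-8 of the optimum.

## Evaluation measures

Against a ground truth `(R*, T)` with `Gamma = |R* - R|`: eta is the mean
absolute error over all pairs, eta_tp over true edges (N_tp of them), eta_tn
over true non-edges, so `eta * p(p-1)/2 = eta_tp N_tp + eta_tn N_tn` exactly;
an empty reference class raises rather than silently returning 0. Applying
eta to every retained draw's partial-correlation transform yields the
posterior error distribution `P(eta)` (per-draw, not the posterior-mean R),
and a point estimate is standardized as `z = (eta_point - mean) / sd` against
it. Posterior shape is summarized by the plug-in entropy (bits) of the
empirical graph frequencies and by the modal graph's empirical frequency
(ties broken by first occurrence, all tied graphs reported) — both computed on
the discrete graph marginal of the retained samples, since the continuous
`K` cannot enter a discrete entropy.

## Synthetic data

The generator mirrors the generative model: an Erdős–Rényi graph at the
requested density; a ground-truth precision from `W_G(delta, D)`,
rejection-sampled until every true edge carries `|r| >= min_abs_partial`
(default 0.25 — draws from a vague G-Wishart otherwise often place near-zero
partials on true edges, which makes recovery unidentifiable rather than hard;
a graph whose retry budget is exhausted, typical when a hub node's degree
makes simultaneously large partials improbable, is redrawn); Gaussian series
with covariance `K^{-1}`; and Dirichlet-multinomial streamline counts with
fixed row totals. `mismatch_rate` flips the edge indicator for that fraction
of pairs inside the streamline generator only — the Gaussian data stay
faithful to the true graph — which is the cleanest model of contradicting
modalities.

Standard study conditions, fixed once: recovery uses p = 10, n = 2000,
density 0.3, floor 0.25 (a regime where the posterior should essentially
solve the problem, so the ROC-area check is a correctness test, not a
horse race); fusion-direction experiments use p = 6, n = 60 with 1000
streamlines per seed region — deliberately data-poor so the fMRI-only
posterior is diffuse and the entropy reduction from consistent streamlines is
observable. At full mismatch every pair's streamline evidence contradicts the
time series (true edges lose support, non-edges gain it), and the variance
comparison for contradicted pairs is therefore made over all pairs.

What the generator does *not* emulate: haemodynamics (no forward BOLD model,
no autocorrelation — rows are i.i.d.), shared-input or time-mixing
corruptions, measurement noise beyond Gaussianity, or realistic tractography
biases (distance dependence, gyral bias). Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to fMRI confounds.

## Numerical choices and limitations

* PD checks are Cholesky-based and failures raise; no eigenvalue clipping
  anywhere.
* Precision draws violating their graph raise (not -inf) in the density, to
  surface programming errors.
* Chain cost is O(p^3) per iteration with small constants; the implementation
  is practical to p of a few tens, not hundreds — the known scale limit of
  exact G-Wishart machinery.
* The exchange step's exactness rests on the auxiliary draws being
  (near-)perfect prior samples; the correction-sweep count trades a small,
  measured bias against runtime (see the enumeration benchmark above).
* Single-edge-flip proposals mix slowly on posteriors with tightly coupled
  edges; for the package's target sizes the cross-chain discrepancy check
  exposes this when it matters.
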