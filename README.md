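# bggm — Bayesian Gaussian graphical models for functional connectivity

`bggm` estimates functional connectivity between brain regions (or any set of
jointly Gaussian variables) as a *joint posterior distribution* over

* a **conditional-independence graph** `G` — which region pairs are directly
  coupled once all other regions are accounted for, and
* the **precision matrix** `K` (inverse covariance), reported as **partial
  correlations** `r_ij = -k_ij / sqrt(k_ii k_jj)` — how strong each direct
  coupling is.

It is aimed at researchers analysing region-averaged fMRI/BOLD time series
who want more than a point estimate: edge *probabilities*, per-edge partial
correlation *distributions*, and principled fusion with diffusion-MRI
tractography. Maximum-likelihood and graphical-LASSO point estimates are
included as comparators, together with the standard reconstruction-error
measures for benchmarking against a known ground truth.

## Model

Observations are n i.i.d. rows of a zero-mean p-variate Gaussian,
`x_i ~ N(0, K^{-1})`, so the likelihood depends on the data only through the
scatter matrix `Sigma = X'X`. Zeros in `K` are conditional independencies, and
the model makes them first-class: a graph prior and a graph-constrained matrix
prior,

    P(G, K | X) ∝ P(X | K) · P(K | G) · P(G)

with

* `P(K | G) = W_G(delta, D)` — the **G-Wishart** distribution, supported on
  positive-definite matrices with zeros off the edge set of `G`; conjugate to
  the Gaussian likelihood (posterior `W_G(delta + n, D + Sigma)`). The vague
  default is `delta = 3`, `D = I`.
* `P(G) = prod_{i<j} theta_ij^{g_ij} (1 - theta_ij)^{1 - g_ij}` — independent
  Bernoulli edges, `theta_ij = 0.5` by default; entries of exactly 0 or 1 act
  as hard constraints (e.g. the homotopy prior, which fixes homotopic
  interhemispheric edges to 1 and forbids all other interhemispheric edges).
* optionally `P(S | G) = prod_j DirMult(s_j | alpha g_j + beta (1 - g_j))` — a
  Dirichlet-multinomial likelihood tying probabilistic-tractography
  streamline counts to the same graph, with `(alpha, beta) = (1, 0.5)`:
  streamlines concentrate on existing connections. Adding this term yields
  the fused posterior `P(G, K | X, S)`.

Inference is by MCMC: single-edge flips accepted through a double-conditional
exchange step (an auxiliary precision drawn from the prior under the proposed
graph makes the intractable G-Wishart normalizing constants cancel),
interleaved with exact conjugate updates of `K`. Posterior samples support
edge probabilities, mean/variance partial correlations, the plug-in entropy of
the sampled graph distribution, the MAP graph and its probability, and
cross-chain convergence checks.

## Worked example

```python
import numpy as np
from bggm import GraphicalModel, ScenarioConfig, make_scenario

# a synthetic study: 6 regions, 300 time points, 30% edge density,
# every true edge carries |partial correlation| >= 0.25
scenario = make_scenario(ScenarioConfig(p=6, n=300, density=0.3,
                                        row_totals=1000, seed=42))

model = GraphicalModel(scenario.timeseries.to_dataframe())
results = model.fit(n_iterations=10_000, burn_in=2000, thin_to=1000,
                    n_chains=2, seed=7)
print(results.summary(top=6))

glasso = model.fit_glasso(lam=100.0)
print(f"graphical-LASSO error z-score vs posterior P(eta): "
      f"{results.z_score_point_estimate(scenario.truth, glasso):+.2f}")
```

prints

```
Bayesian Gaussian graphical model
==============================================
regions:             6
observations:        300
likelihood:          time series only
prior:               W_G(delta=3, D) x Bernoulli edges
chains x iterations: 2 x 10000
retained draws:      2000
acceptance rate:     0.118
posterior density:   0.229
entropy (bits):      4.627
MAP probability:     0.333
unique graphs:       8.7%
convergence:         PASS (max edge-probability discrepancy 0.032)
top 6 edges by inclusion probability:
region_a region_b  P(edge)  mean r  sd r
region_0 region_5    1.000   0.656 0.027
region_1 region_5    1.000  -0.628 0.028
region_1 region_4    0.682  -0.069 0.057
region_4 region_5    0.115  -0.002 0.021
region_0 region_1    0.108   0.002 0.019
region_0 region_4    0.096   0.001 0.017

graphical-LASSO error z-score vs posterior P(eta): +5.42
```

Reading this: the two strong true couplings are recovered with probability
1.0 and tight partial-correlation distributions; a weaker true edge (1–4) is
genuinely uncertain (P = 0.68, and its partial-correlation spread, sd 0.057,
reflects the on/off mixture); non-edges sit near the prior floor with mass at
zero. The posterior entropy (4.6 bits over 2000 draws) says many graphs remain
plausible — information a point estimate hides. The positive z-score means the
LASSO point estimate's reconstruction error lies more than five standard
deviations above the posterior's own error distribution `P(eta)`.

The same pipeline runs from the shell:

```bash
bggm simulate --p 6 --n 300 --seed 42 --out scenario/
bggm fit config.yaml          # or: bggm fuse config.yaml (with streamlines)
bggm glasso --timeseries scenario/timeseries.csv --lam 100 --out point/
bggm evaluate --truth-r scenario/partials_true.csv \
              --truth-mask scenario/mask_true.csv \
              --estimate point/partial_correlations.csv
```

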