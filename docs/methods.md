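# Methods

## Model family

All models share the likelihood `Y ~ MVN(μ, V)` over tip values of a rooted
time tree scaled to unit height (the original height is kept as a scale
factor so half-lives can be reported in absolute time).  Node times run
forward from the root (root = 0).

**Multi-optima.**  A regime painting assigns every branch (and the root) to
one of K regimes; a branch carries the regime of its parent node, so
painting a node starts a new regime below it.  The mean is `μ = W θ`, where
the Hansen design matrix W contains exponentially discounted occupancy
weights: a lineage segment of regime k on `[t_a, t_b]` for a tip at depth
`T_i` contributes `e^{−α(T_i − t_b)} − e^{−α(T_i − t_a)}` to `W[i, k]`, and
the residual root mass `e^{−α T_i}` is assigned to the root's regime.  There
is no separate ancestral-state parameter: the root lineage is treated as
having been at its regime's optimum, which keeps rows summing to one.  The
residual covariance is the OU form
`V[i,j] = v e^{−α d_ij} (1 − e^{−2α s_ij})`, with `s` the MRCA time and `d`
the patristic distance of the pair.

**Direct effect.**  Mean-centered predictors enter the mean directly
(`μ += X β`); residuals are OU.  Interpretable as a single-optimum model
whose optimum lies along the regression line.

**Adaptive.**  The optimum tracks a Brownian predictor x with rate σ²_x.
Writing ρ = ρ(αT) = 1 − (1 − e^{−αT})/(αT), the tip-level (evolutionary)
slope is β·ρ — the deterministic definition of the evolutionary regression —
and the mean is `μ = W θ + ρ X β`.  The predictor's history inflates the
residual covariance:

    V = V_OU + β_i β_j σ²_x M(s_ij),
    M(s) = α² I(s) − 2 ρ α J(s) + ρ² s,

where `J(s) = ∫₀ᵀ e^{−α(T−u)} min(u, s) du` and
`I(s) = ∫₀ᵀ∫₀ᵀ e^{−α(2T−u−w)} min(u, w, s) du dw` are elementary integrals
of the exponentially discounted shared predictor history.  These closed
forms are derived from the joint Gaussian distribution of the Brownian
predictor and the OU response; the test suite verifies them against direct
numerical quadrature and against Euler–Maruyama simulation of the SDE.
Limits: as α→∞, M→0 and the model reduces to the direct-effect model; as
α→0 (with σ²_y = 2αv fixed), M = O(α²) and V reduces to the
Brownian-motion covariance `σ²_y s`.  ρ(0) is defined by continuity as 0.
Below αT = 0.01 the closed form of M is replaced by its exact series
expansion to O(α⁴) (the closed form loses precision to catastrophic
cancellation there; the series' relative truncation error is O((αT)³)).
The adaptive model requires an ultrametric tree (ρ assumes a common tip
depth) and supports one predictor; with varying slopes, the pair covariance
uses β_i β_j with β taken from each tip's regime — an approximation to a
regime-varying slope history that changes along a lineage.  The predictor's
Brownian variance σ²_x is estimated jointly by default (half-Cauchy prior,
plus a root-state parameter x₀ ~ Normal(0, 2)); a plug-in GLS estimate from
the observed predictor is available instead.

**Varying effects.**  Regime-specific intercepts θ_k and slopes β_k can be
independent with fixed priors (`slope_structure="by_regime"`), or partially
pooled (`multilevel="varying_effects"`):
`(θ_k, β_k) ~ MVN((θ̄, β̄), diag(σ_θ, σ_β) R diag(σ_θ, σ_β))` with a 2×2 LKJ
correlation prior (η = 4).  Both centered and non-centered
parameterizations are implemented; the non-centered form usually samples
better when regimes are few (the funnel benchmark in the test suite shows
it removes the divergences of the centered form).

**Measurement error.**  Reported response SEs are marginalized exactly: for
a Gaussian model the latent-true-value formulation integrates to adding
`se²` to the covariance diagonal, so the fast path is also the exact one.
Predictor SEs are handled with explicit latent true values (weak
Normal(observed, 10·SE) priors, overridable), which feed both the mean and
the predictor's Brownian likelihood.

## Priors

Defaults are constructed from the data following one guideline per
parameter, all overridable:

| parameter | default | rationale |
|---|---|---|
| t½ | log-normal solving P(t½<0.1)=P(t½>1)=0.10 | spans near-instantaneous adaptation to Brownian-like inertia on a unit tree |
| v | Exponential with mean = var(Y) (uniform[0,4·var], half-Cauchy available) | current among-species variance anchors the stationary variance |
| θ, θ̄ | Normal(mean(Y), 1) | optima live near the observed response range |
| β, β̄ | Normal(OLS slope, max(1, 2·OLS)) (β̄ sd ×0.25) | instantaneous adaptation reduces to ordinary regression |
| σ_θ, σ_β | Exponential(1); R ~ LKJ(4) | weakly regularizing hierarchy |

Prior-predictive simulation (`evaluate.prior_predictive` /
`phylou check --mode prior`) is the recommended way to vet these on a real
dataset.

## Sampling

Positive parameters are sampled on the log scale and the intercept/slope
correlation through atanh, with Jacobians.  The sampler is a self-contained
No-U-Turn sampler (slice variant): dual-averaging step-size adaptation to a
0.9 acceptance target (the half-life / stationary-variance pair forms a
correlated ridge that diverges at looser settings), a diagonal mass matrix
estimated from the middle
warmup window, a max tree depth of 10, and divergence counting (energy
error > 1000); more than 10% divergences triggers a warning recommending
the non-centered parameterization.  Defaults are 2 chains × 4000 iterations
(half warmup), and fixed seeds give bit-identical draws.  Gradients are
analytic for every parameter in non-adaptive models (including dV/dα and
the design-matrix derivative) and for all but (log t½, log v) in adaptive
models, where those two use central finite differences; the accept/reject
step always uses the exact log posterior, so the algorithm remains exact
MCMC regardless of gradient accuracy.  A 1e-10·v jitter is added to V's
diagonal before factorization; failure after jitter raises with the
smallest eigenvalue, never silently.

Convergence is judged by rank-based split R̂ (< 1.1) and effective sample
size (≥ 100), computed via ArviZ behind `phylou.inference.diagnostics`.

## Model comparison

The pointwise log-likelihood decomposes the correlated MVN by default into
leave-one-out conditional normals `log p(y_i | y_−i)` (Schur complement);
the marginal mode (diagonal of V) is retained for cross-checks and tagged
in outputs.  PSIS-LOO follows the standard recipe (tail
`min(0.2 S, 3 √S)`, Zhang–Stephens generalized-Pareto fit, smoothed
quantile replacement, truncation at the raw maximum); k ≤ 0.5 good, ≤ 0.7
acceptable, above unreliable.  WAIC is `lppd − Σ_i var_s(pll)`.  Marginal
likelihoods use the iterative optimal-bridge estimator with a
moment-matched normal proposal on the unconstrained scale (half the draws
fit the proposal, half enter the iteration; relative tolerance 1e-8), and
the reported SE uses the independent-draws approximation.  Bayes factors
can be conservative under vague priors; they are reported with the SEs of
the underlying marginals.

## Synthetic data

The simulator draws Yule (birth-death) trees with a given number of extant
tips via the general sampling approach (a uniform time slice while exactly
n tips are extant — avoiding the zero-length terminal cherry of stopping at
a birth event, which would make V singular), scaled to unit height.  Regime
paintings place K−1 regimes on random internal clades of 5–40 tips (root
carries the K-th), regenerating until every regime covers ≥ 5 tips.
Predictors are Brownian with σ²_x = 1; responses are drawn from the exact
model MVN conditional on the predictors; measurement noise is
Normal(0, sd) with the same sd reported as the SE.  All randomness flows
from one master seed through fixed-counter child streams, so adding a
random step never perturbs earlier ones.

The standard validation fixture is a ~100-tip tree with 4 clade regimes,
θ = (1, 2, 3, 4), per-regime optimal slopes β = (0.75, 0.5, 0.35, 0.25),
t½ = 0.1, v = 0.01, and 0.01 measurement noise on both variables.  What the
simulator does *not* emulate: non-ultrametric (fossil) sampling,
non-Gaussian noise, regime-dependent diversification, and within-species
sampling structure — passing recovery tests therefore demonstrates internal
consistency of model and sampler, not robustness to real-data violations.

## Validation design and problem sizes

The recovery study simulates 2-regime direct-effect datasets (θ = (0.5,
1.5), β = 0.4, v = 0.01, measurement sd 0.01 on both variables) at
half-lives 0.1, 0.25, and 0.75 — fast adaptation to near-Brownian motion —
and refits the matching model, recording 95% CI coverage of t½, v, θ, β.
Desk scale, chosen so the full suite runs comfortably on one CPU: 30-tip
trees, 2 chains × 350 post-warmup iterations, 6 replicates per half-life in
the test suite (4 in the acceptance script).  The predictor's 0.01
measurement error is negligible against its unit Brownian variance and is
handled by plug-in there; latent-predictor machinery is exercised
separately.  Posterior intervals widen as t½ approaches tree height, as
theory predicts.  The regime-uncertainty study (20 replicates) plants a
smallest regime whose predictor values are compressed 20-fold and checks
that its slope interval is the widest.

## Known limitations

* Single response trait (no multivariate co-evolution) and constant α, σ_y
  across branches.
* The adaptive model: one predictor, ultrametric trees only.
* Mk reconstruction maximizes over rates and assigns maximum-likelihood
  states; regime-painting uncertainty is not propagated into the OU fit
  (stochastic character mapping is out of scope).  The Mk root state
  distribution is uniform — an assumption, since reference implementations
  differ here.
* Bridge-sampling SEs assume independent draws and will understate error
  for sticky chains.
* The NUTS implementation is plain Python/NumPy; fits beyond a few hundred
  tips will be slow.
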