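# Methods

## Problem and models

`crashspat` analyses yearly crash counts on the segments of a single
freeway corridor that has been split into n homogeneous segments (here
n = 154 by default), labelled 1..n along the chain. Two distinct spatial
mechanisms are modelled:

* **spatial autocorrelation** — adjacent segments share unobserved risk
  factors (terrain, weather exposure), captured by a structured random
  effect φ with an intrinsic conditional autoregressive (ICAR) prior;
* **spatial spillover** — the *observed* design of a neighbouring segment
  (its curvature, grade, bridges, ramps) affects crashes on the targeted
  segment, captured by extra regressors built from neighbour covariates.

All three model variants share the Poisson observation layer
Y_i | λ_i ~ Poisson(λ_i) and a log link:

| variant | log λ_i |
|---|---|
| `car` | α + β₀ log DVKT_i + β′X_i + θ_i + φ_i |
| `spillover` | α + β₀ log DVKT_i + β′X_i + β_adj′X_adj,i + θ_i |
| `hybrid` | α + β₀ log DVKT_i + β′X_i + β_adj′X_adj,i + θ_i + φ_i |

θ_i ~ N(0, 1/τ_h) is an exchangeable heterogeneity effect absorbing
extra-Poisson dispersion; φ has the ICAR prior with conditional law
φ_i | φ_{-i} ~ N(mean of neighbours, 1/(τ_c m_i)), m_i the neighbour
count, equivalently the improper joint density ∝
τ_c^{(n−1)/2} exp(−τ_c/2 Σ_{i<j} w_ij (φ_i − φ_j)²) of rank n−1 on a
connected graph. We write σ_h = 1/τ_h and σ_c = 1/τ_c; note both are
**variances** (σ_h is the marginal variance of θ_i, σ_c the conditional
variance scale of the ICAR), despite the σ symbol that is conventional in
this literature. Reported σ values are posterior summaries of the
transformed draws 1/τ.

Priors are deliberately vague: N(0, 10⁴) on α, β₀ and every element of β
and β_adj; gamma(0.001, 0.001) on τ_h and τ_c. All are configurable
through `PriorConfig`.

## Spatial weights, spillover covariates, Moran's I

Weights are binary first-order adjacency: w_ij = 1 iff segments i and j
touch. On a chain the weight matrix is tridiagonal with row sums 1 at the
endpoints and 2 inside, total weight 2(n−1). Higher-order or
distance-decay weights are out of scope.

Adjacent (spillover) covariates follow the chain-specific construction:
continuous factors take the length-weighted mean of the two neighbours
(endpoints copy their single neighbour); binary factors take an
any-neighbour indicator (endpoints copy the neighbour). A general-graph
variant (`adjacent_continuous_graph`, length-weighted mean over all graph
neighbours) is provided as an explicit extension for non-chain networks.

Before modelling, a Pearson screen drops any adjacent variable whose
correlation with its own targeted-segment counterpart exceeds |r| > 0.6
(strict inequality, magnitude only); the adjacent member of the pair is
dropped, never the targeted one. On real corridors the bridge indicator
typically fails this screen because an any-neighbour indicator of a
common feature is close to saturated.

Global Moran's I with unstandardized binary weights screens the raw
counts for clustering. E[I] = −1/(n−1) under the null; the closed-form
null variance is available under both the normality and the randomization
(permutation) assumption. Randomization is the default, standard for
counts; on a chain the two differ little. "Significant clustering at the
95% level" is interpreted two-sided, |z| > 1.96.

## Exposure scale

DVKT (daily vehicle kilometres travelled) = AADT × length is the exposure
variable. Tables store it on the 10³ km·pcu scale for readability, but the
model's exposure column is `log_dvkt = log(1000 · dvkt)`, i.e. raw
km·pcu units. Because exposure enters as β₀·log DVKT with estimated β₀,
the scale choice only shifts the intercept; the raw-unit convention keeps
intercepts on the scale practitioners report for corridor data of this
kind (intercepts near −8 to −9 with mean log exposure near 10.7).

## Sampler

A from-scratch Metropolis-within-Gibbs sampler; one sweep is

1. element-wise adaptive random-walk Metropolis on α and each slope;
2. a vectorized single-site random-walk Metropolis sweep over θ (sites
   are conditionally independent, so element-wise accept/reject of a
   simultaneous proposal is exact);
3. for CAR variants, a single-site sweep over φ run over graph-colour
   blocks — no two sites of a colour are neighbours, so each block update
   is a valid conditionally-independent Metropolis step and the whole
   sweep is equivalent to a sequential scan (a chain needs 2 colours);
   afterwards φ is re-centered to sum zero with the removed mean absorbed
   into α, which leaves the linear predictor unchanged and restores
   intercept identifiability under the improper ICAR prior;
4. conjugate Gibbs draws τ_h ~ gamma(a + n/2, b + Σθ²/2) and
   τ_c ~ gamma(a + (n−1)/2, b + Σ_{i<j} w_ij(φ_i−φ_j)²/2). The (n−1)/2
   exponent is the rank of the ICAR precision on a connected graph; the
   sampler refuses disconnected weight graphs.

**Centering.** Covariates (including log exposure) are centered
internally; slopes are unaffected and the intercept is back-transformed
per draw (α = α_c − Σ_j β_j x̄_j). Priors are evaluated on the
original-scale parameters — a slope move also moves the original
intercept, and both prior terms enter the acceptance ratio — so the
sampled posterior is exactly the stated model, while mixing improves
greatly because the intercept decorrelates from the slopes.

**Adaptation.** Each proposal scale adapts every `adapt_window` (default
100) iterations by log-scale Robbins-Monro steps toward `adapt_target`
(default 0.44, the classic single-component target), during burn-in only;
scales are frozen afterwards, so the post-burn-in chain is a fixed-kernel
Markov chain. Reported acceptance rates cover the post-burn-in phase.

**Initialization.** α at log of the mean count, slopes and random effects
at zero, both precisions at 1 — a finite-posterior start matching common
practice for these hierarchical count models.

**Defaults.** 150,000 iterations with 100,000 burn-in (the conventional
full-length run for these models), thinning 10. Tests and the acceptance
script use shorter chains (6k–15k iterations at n = 154), which this
sampler's vectorized updates make adequate for the summaries they check;
the chain lengths used are stated in each test.

**Determinism.** A single `numpy` Generator seeded from `McmcConfig.seed`
drives every draw; identical inputs and seed give bit-identical output.

## Assessment

* **Summaries** are posterior means/SDs and equal-tailed quantile credible
  intervals; a coefficient is flagged significant at the highest level
  (90/95) whose interval excludes zero. The flag is meaningless for the
  positive-support variance parameters σ_h, σ_c; their intervals are
  reported without a flag.
* **DIC** = D̄ + p_D with p_D = D̄ − D̂, D̄ the posterior mean of the
  stored deviance −2 log p(Y | λ) and D̂ the deviance at the posterior
  means of *all* stochastic nodes entering log λ (coefficients, θ, φ).
  DIC is not invariant to the plug-in choice; the all-stochastic-parents
  convention matches classic BUGS behaviour. Both identities are exact by
  construction and asserted to 1e-9 in tests. No decision threshold on
  DIC differences is encoded; raw values are reported.
* **η = sd(φ)/(sd(θ) + sd(φ))**, the share of extra-Poisson variation
  attributed to spatial autocorrelation, is computed per retained draw
  (SDs across segments, ddof = 1) and averaged; the alternative — SDs of
  the posterior-mean fields — is available via `method="sd_of_means"` and
  is typically smaller because averaging shrinks θ more than φ.
* **Convergence** uses batch-means Monte-Carlo error (≈√m batches) per
  scalar parameter; parameters with MC-error/SD ≥ 0.05 are flagged, and
  constant traces are reported as degenerate rather than flagged.
  Single-chain design; multi-chain diagnostics (Gelman–Rubin) and
  WAIC/LOO are deliberate non-goals.

## Synthetic corridors

The generator emulates the corridor the models target rather than any
deposited dataset (none exists): a chain of 154 segments with

* lognormal lengths, mean 1.0 km, CV 0.35, floored at the 0.15 km minimum
  homogeneous-segment length;
* gamma curvature (mean 1.77, SD 1.27, in 0.1/km) and grade (mean 0.741,
  SD 0.568, in %); Bernoulli bridge (p = 0.5) and ramp (p = 0.208)
  indicators;
* lognormal corridor AADT (mean 44,300 pcu/day, CV 0.12), nearly constant
  along the route as is typical for a tolled freeway, so DVKT moments
  (mean ≈ 44.3, SD ≈ 17 on the 10³ scale) are driven mainly by length
  variation.

Only the moments are calibrated; the distributional families (lognormal,
gamma, Bernoulli) are the package's choice, since corridors publish
moments, not samples. Crash counts are then drawn from the chosen model
variant itself: θ ~ N(0, σ_h), φ an *exact* ICAR draw — a zero-mean
Gaussian on the orthogonal complement of the constant vector via
eigen-decomposition of the graph Laplacian, cheap at a few hundred
segments and exactly sum-to-zero, with
E[Σ_{i<j} w_ij (φ_i − φ_j)²] = (n−1)σ_c — and Y_i ~ Poisson(exp(log λ_i)).
A truth record (θ, φ, λ, parameters) accompanies every dataset to support
recovery tests. Scenarios with log λ > 30 are refused as parameterization
errors.

The `kaiyang_like_preset` scenario uses published hybrid-model posterior
means as generating truth (α = −8.27, β₀ = 0.886, curvature 0.106, grade
0.170, adjacent curvature −0.150, adjacent grade 0.227, σ_h = 0.021,
σ_c = 0.032), which places the implied mean crash count near the observed
4.46 per segment. One caveat matters when interpreting simulations: σ_c
is a *conditional* variance, and on a long chain the ICAR's *marginal*
variation is much larger (random-walk-like), so simulated corridors carry
a heavy-tailed multiplicative inflation of the mean count (typically
≈1.5×, occasionally more). Typical simulated corridors therefore sit
within a factor of two of the target mean, but individual seeds can
overshoot — a property of the generative ICAR itself, not of the fitting
code.

What the generator does **not** emulate: real corridors have engineered
alignment (curvature and grade are serially dependent by design, not
i.i.d.), AADT varies with interchanges, and crash assignment to segments
carries location error. Passing recovery and model-selection tests on
these synthetic corridors therefore demonstrates correctness of the
machinery under the stated model, not field validity of the model on any
particular freeway.

## Numerical choices and limitations

* Covariates enter on their natural scales (no standardization), so
  coefficients are directly comparable to published per-unit estimates.
* Zero-covariate and no-exposure models are permitted (used by the
  grid-integration cross-check); constant covariate columns are legal but
  uninformative.
* The correlation screen errors on zero-variance columns rather than
  silently passing them; `build_spillover` keeps constant adjacent
  columns out of the screen and retains them.
* Quantile intervals use linear-interpolation sample quantiles; with
  degenerate (constant) draws both interval endpoints equal the value.
* Proper-CAR (ρ-parameterized) priors, multivariate CAR, zero-inflated
  variants, spatially varying coefficients, and temporal extensions are
  out of scope.
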