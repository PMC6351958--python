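# crashspat

Bayesian spatial crash-frequency analysis for freeway segment chains.

Road-safety analysts modelling crash counts on the segments of a single
freeway face two distinct spatial mechanisms: **spatial autocorrelation**
(adjacent segments share unobserved risks such as terrain and weather)
and **spatial spillover** (the *observed* design of a neighbouring
segment — its curvature, grade, bridges, ramps — affects crashes on the
targeted segment). `crashspat` implements both, separately and together,
for a corridor split into n homogeneous segments in chain order:

* spillover ("adjacent") covariate construction — length-weighted
  neighbour means for continuous factors, any-neighbour indicators for
  binary ones — with a Pearson screen dropping adjacent variables that
  duplicate their targeted counterpart (|r| > 0.6);
* global Moran's I with unstandardized binary first-order weights and a
  closed-form z-score (randomization or normality null);
* three Poisson count models fit by a from-scratch adaptive
  Metropolis-within-Gibbs sampler, sharing
  Y_i | λ_i ~ Poisson(λ_i) and differing in the link:
  - **car**: log λ_i = α + β₀ log DVKT_i + β′X_i + θ_i + φ_i
  - **spillover**: log λ_i = α + β₀ log DVKT_i + β′X_i + β_adj′X_adj,i + θ_i
  - **hybrid**: both φ_i and the spillover terms
  with exchangeable heterogeneity θ_i ~ N(0, 1/τ_h), an intrinsic CAR
  (Besag) prior on φ with sum-to-zero centering, diffuse N(0, 10⁴) and
  gamma(0.001, 0.001) priors, and DVKT = AADT × length as exposure;
* posterior summaries with 90/95% credible intervals and significance
  flags, DIC (D̄ + p_D) model comparison, the spatial proportion
  η = sd(φ)/(sd(θ) + sd(φ)), and batch-means convergence checks;
* a calibrated synthetic-corridor generator (chain of 154 segments,
  moment-matched covariates, exact ICAR field draws, truth records) so
  every stage is testable without proprietary crash data.

See `docs/methods.md` for model details, sampler design, and the
generator's scope.

## Worked example

Simulate a corridor from the calibrated hybrid scenario, check the counts
for spatial clustering, and fit the hybrid model:

```python
from crashspat import (kaiyang_like_preset, simulate_dataset,
                       build_chain_weights, morans_z, ModelSpec,
                       PriorConfig, McmcConfig, run_mcmc, full_summary)

scn = kaiyang_like_preset()
scn.seed = 7
table, spill, truth = simulate_dataset(scn)

res = morans_z(table["crash_count"].to_numpy(),
               build_chain_weights(len(table)))
print(f"Moran I = {res.I:.3f}, z = {res.z:.2f}")

spec = ModelSpec("hybrid", covariates=("curvature", "grade"),
                 spillover_covariates=("curvature_adj", "grade_adj"))
cfg = McmcConfig(iterations=15_000, burn_in=5_000, thin=10, seed=1)
samples = run_mcmc(table, spill, spec, PriorConfig(), cfg)
summary = full_summary(samples)
print(summary.to_frame().round(3).to_string(index=False))
print(summary.dic, summary.eta)
```

Output:

```
Moran I = 0.479, z = 6.12
    parameter   mean    sd  ci90_low  ci90_high  ci95_low  ci95_high significance
        alpha -8.297 1.414   -10.457     -5.966   -11.060     -5.654           95
     log_dvkt  0.867 0.133     0.649      1.078     0.607      1.120           95
    curvature  0.157 0.040     0.094      0.225     0.080      0.237           95
        grade  0.270 0.072     0.156      0.386     0.136      0.411           95
curvature_adj -0.086 0.070    -0.201      0.022    -0.227      0.042         none
    grade_adj  0.235 0.089     0.085      0.375     0.068      0.401           95
      sigma_h  0.017 0.018     0.001      0.055     0.001      0.063          n/a
      sigma_c  0.047 0.015     0.027      0.075     0.024      0.083          n/a
DIC: {'D_bar': 638.7, 'D_hat': 591.7, 'p_D': 47.0, 'DIC': 685.6}   eta: 0.907
```

The z-score of 6.12 confirms the simulated counts are spatially
clustered. The fit recovers the generating coefficients (truth: exposure
0.886, curvature 0.106, grade 0.170, adjacent curvature −0.150, adjacent
grade 0.227): each 95% interval covers its truth, with the exposure
coefficient's interval including 1 (a near-linear crash–exposure
relationship). η ≈ 0.91 attributes most extra-Poisson variation to the
spatial field, consistent with how this corridor was simulated, and the
significance column flags which effects the data pin down at the 90/95%
credible level. `sigma_h`/`sigma_c` are the heterogeneity and spatial
variance parameters (1/τ).

The same pipeline is available from the shell:

```bash
crashspat simulate --preset kaiyang-like --seed 7 --out seg.csv --truth truth.json
crashspat moran --in seg.csv
crashspat spillover --in seg.csv --out spill.csv --report screen.json
crashspat fit --model hybrid --in seg.csv --seed 1 --out fit.csv
crashspat compare --in seg.csv --seed 1        # DIC table for all variants
```

Input CSVs need the columns
`segment_id,length,curvature,grade,bridge,ramp,aadt[,dvkt],crash_count`
with ids 1..n in chain order.

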