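# gaussmeta

One- and two-stage meta-analysis of Gaussian individual participant data
(IPD), for meta-analysts and statisticians who want to check — rather than
assume — that the number of stages used to fit a model does not change the
answer.

When patient-level data from several randomised trials are available, the
treatment effect β can be estimated either in **two stages** (estimate
β̂ᵢ and its standard error within each study, then pool with weights) or in
**one stage** (fit a single model to all patients with the study structure
encoded in it). `gaussmeta` implements both procedures for the two models
that matter in practice, plus the small-sample theory needed to compare
them:

* **Fixed-effect model** — yᵢⱼ = (α + aᵢ) + β xᵢⱼ + εᵢⱼ with treatment
  coded x = ±0.5 and εᵢⱼ ~ N(0, σᵢ²). Under study-specific σᵢ² the
  one-stage weighted fit and two-stage inverse-variance pooling
  (wᵢ = 1/v̂ᵢ, v̂ᵢ = σ̂ᵢ²(1/n_t + 1/n_c)) are *identical*; under a shared σ²
  the sample-size-weighted two-stage pool recovers the patient-level OLS
  fit exactly.
* **Variance formulas** — the asymptotic inverse-variance variance
  1/Ŵ (Ŵ = Σ 1/v̂ᵢ), which is biased downward when studies are small
  because the σ̂ᵢ² are estimates, and a small-sample formula
  1/Ŵ + Σᵢ 4 wᵢ²(β̂ᵢ − β̂)² / ((nᵢ − 2) Ŵ²) that is unbiased for the true
  sampling variance of β̂ to second order. A theory module computes the
  expected values of both (deterministic quadrature where a closed form
  exists, Monte Carlo otherwise) relative to the OLS variance.
* **Random-effects model** — βᵢ = β + bᵢ with bᵢ ~ N(0, τ²), fixed study
  intercepts and study-specific σᵢ². τ² is estimated by REML (two-stage: on
  the study estimates with stage-1 variances fixed; one-stage: jointly with
  all σᵢ² on collapsed per-arm sufficient statistics), and confidence
  intervals use the Kenward–Roger small-sample correction: an inflated
  variance and Satterthwaite-type degrees of freedom, which in the balanced
  equal-variance case reduce exactly to the t interval on the I study
  estimates (df = I − 1).
* **Simulation harness** — paired replications (both procedures fit the
  same simulated datasets) reporting bias, relative precision gain (%) and
  coverage, each with Monte Carlo standard errors.

## Worked example

```python
import gaussmeta as gm

bundle = gm.simulate_meta_ipd(gm.DGMConfig(I=10, beta=0.0, tau2=1.0, seed=5))
fit2, res2 = gm.fit_two_stage_re(bundle.ipd)   # REML + Kenward-Roger
fit1, res1 = gm.fit_one_stage_re(bundle.ipd)
print(f"two-stage: beta = {fit2.beta_hat:.4f} "
      f"95% CI ({res2.ci_low:.4f}, {res2.ci_high:.4f}) "
      f"tau2 = {fit2.tau2_hat:.4f} KR df = {fit2.df_kr:.2f}")
print(f"one-stage: beta = {fit1.beta_hat:.4f} "
      f"95% CI ({res1.ci_low:.4f}, {res1.ci_high:.4f}) "
      f"tau2 = {fit1.tau2_hat:.4f} KR df = {fit1.df_kr:.2f}")
```

prints

```
two-stage: beta = -0.6471  95% CI (-1.2391, -0.0551)  tau2 = 0.5833  KR df = 8.90
one-stage: beta = -0.6468  95% CI (-1.2469, -0.0468)  tau2 = 0.5812  KR df = 8.23
```

The two procedures fit the same random-effects model and agree in the
pooled effect to the third decimal; the small residual differences come
from the stage-1 residual variances being plugged in (two-stage) versus
re-estimated jointly (one-stage), and from the slightly different
Kenward–Roger degrees of freedom. More narrative scripts live in
`examples/` (fixed-effect equivalences, theory curves, the simulation
study), and a thin CLI (`gaussmeta fit|simulate-data|simulate|curves`)
exposes the same analyses for CSV files.

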