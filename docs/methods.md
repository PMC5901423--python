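# Methods

## Models and notation

Patient j in study i (i = 1..I, j = 1..nᵢ) has a Gaussian outcome yᵢⱼ and a
treatment indicator xᵢⱼ coded −0.5 (control) / +0.5 (treated), so that under
1:1 randomisation the intercept is the study mean and the coefficient of x
is the treatment effect. The package fits:

* **model I** — yᵢⱼ = α + β xᵢⱼ + εᵢⱼ, common residual variance (no study
  structure; mainly a degenerate reference);
* **model II** — yᵢⱼ = (α + aᵢ) + β xᵢⱼ + εᵢⱼ with fixed study intercepts,
  the "fixed-effects meta-analysis", under either a shared σ² or
  study-specific σᵢ²;
* **model IV** — fixed per-study treatment effects (no pooled β; reported
  per study);
* **model V** — βᵢ = β + bᵢ, bᵢ ~ N(0, τ²), fixed study intercepts,
  study-specific σᵢ²: the "random-effects meta-analysis".

Stage 1 of any two-stage analysis is per-study OLS of y on x:
β̂ᵢ = ȳ_T − ȳ_C, σ̂ᵢ² = RSSᵢ/(nᵢ − 2), v̂ᵢ = σ̂ᵢ² cᵢ with cᵢ = 1/n_t + 1/n_c
(= 4/nᵢ under balance). The cᵢ form is used everywhere rather than the 4/nᵢ
shorthand so unbalanced arms are handled exactly.

## Fixed-effect estimation and the two variance formulas

With study-specific variances, the estimator is the inverse-variance
weighted mean β̂ = Σ wᵢ β̂ᵢ / Ŵ, wᵢ = 1/v̂ᵢ, Ŵ = Σ wᵢ. The one-stage
realisation solves the weighted normal equations on the patient-level
design (study dummies + x) with per-row precision 1/σ̂ᵢ², the σ̂ᵢ² estimated
within study; this is algebraically identical to the two-stage pool in both
the point estimate and the variance, and the test suite pins the identity
at 10⁻¹⁰ on random fixtures. With a shared variance, the sample-size
weights wᵢ = n_t n_c/nᵢ reproduce the OLS fit; the shared σ̂² is
reconstructed from the summaries *including* the between-study slope
lack-of-fit term, σ̂² = [Σ RSSᵢ + Σ wᵢ(β̂ᵢ − β̂)²]/(N − I − 1), so the
recovery is exact to machine precision rather than only asymptotic. (A
pooled-within-study alternative, df N − 2I, is available via
`sigma2_pooling="within"`.)

Two variance estimators accompany the study-specific estimator:

* **asymptotic**: Var̂(β̂) = 1/Ŵ, which treats the σ̂ᵢ² as known;
* **small-sample**: Var̂(β̂) = 1/Ŵ + Σᵢ 4 wᵢ²(β̂ᵢ − β̂)²/((nᵢ − 2) Ŵ²).

The second formula comes from a second-order expansion in the σ̂ᵢ² around
their true values. Two effects of exactly equal size
Δ = (2/W²) Σ wᵢ(1 − wᵢ/W)/(nᵢ − 2) appear: the true sampling variance of β̂
exceeds the ideal 1/W by Δ (estimated weights cost precision), and the
plug-in 1/Ŵ underestimates 1/W by the same Δ. Since
E[(β̂ᵢ − β̂)²] = v̂ᵢ(1 − wᵢ/W) at the true weights, the observed squared
deviations estimate the per-study factor, and the correction enters with
coefficient 4 (= 2 + 2). A direct Monte Carlo check (20 000 replicates,
I = 5, n = 20) gives an empirical variance ratio of 1.095 versus the OLS
variance; the small-sample formula averages 1.094 while the asymptotic one
averages 0.913. The df divisor nᵢ − 2 (the per-study residual df) is used
in Var(σ̂ᵢ²) = 2σᵢ⁴/(nᵢ − 2) and is exposed as `df_offset` so the
alternative nᵢ − 1 reading can be tested; a full-regression simulation in
the test suite confirms nᵢ − 2.

Fixed-effect confidence intervals default to normal quantiles with the
asymptotic variance; the small-sample variance is available behind the
`variance="small_sample"` flag.

## Expected-variance theory curves

For I studies of common size n and common true σ², the module compares
E[two-stage formula] with E[OLS variance] = σ²c/I. Writing
σ̂ᵢ² = σ²Qᵢ/m with Qᵢ ~ χ²_m, m = n − 2, the asymptotic-formula expectation
is (cσ²/m)·E[1/S], S = Σ 1/Qᵢ. This is evaluated deterministically via the
Laplace-transform identity E[1/S] = ∫₀^∞ (E[e^(−t/Q)])^I dt; the inner
expectation is integrated in w = log q, where the exponent is strictly
concave so a single Laplace window suffices, and the outer integral is
rescaled so its decay happens at O(1). The quadrature reproduces the exact
identity E[1/S] = m at I = 1 to 10⁻⁷ across m = 2…10⁴ and matches Monte
Carlo within its error elsewhere. No closed form is available for the
small-sample formula's expectation, so Monte Carlo is the primary method
there; the default estimator Rao–Blackwellises it by drawing only the
variance estimates and integrating the effect estimates out analytically
given the weights, leaving Monte Carlo noise far below the curve effects
(the `estimator="full"` and `sampler="ols"` options simulate effect
estimates and full per-study regressions for cross-checks). Ratios are
invariant to σ² (scale cancels), sit below 1 (asymptotic) and above 1
(small-sample) for every n in the default grid 4–100, converge to 1 as
n → ∞, and depend only weakly on I.

## Random-effects REML and the Kenward–Roger correction

**Two-stage.** Given stage-1 pairs (β̂ᵢ, v̂ᵢ) with the v̂ᵢ treated as fixed
and known, τ̂² maximises the restricted log-likelihood of
β̂ᵢ ~ N(β, τ² + v̂ᵢ) by bounded scalar search on [0, ~10× the spread of the
β̂ᵢ]; a negative maximiser returns the boundary value 0, at which all
downstream quantities are evaluated (no positive floor). The pooled effect
is the (τ̂² + v̂ᵢ)⁻¹-weighted mean.

**One-stage.** The restricted likelihood of model V collapses exactly onto
per-study sufficient statistics (arm-mean difference dᵢ, residual sum of
squares RSSᵢ):

    −2 ℓ_R = Σ [(nᵢ−2) log σᵢ² + RSSᵢ/σᵢ²] + Σ log(τ² + cᵢσᵢ²)
             + log Σ uᵢ + Σ uᵢ(dᵢ − β̃)²,   uᵢ = 1/(τ² + cᵢσᵢ²),

including for odd study sizes: the arm-sum coordinate that also carries β
when arms are unbalanced cancels against the fixed-intercept determinant
term through a Schur-complement identity, so the collapse involves no
approximation. The (I+1)-dimensional maximisation over (τ², σ₁²…σ_I²) uses
L-BFGS-B with an analytic gradient, log-parameterised σᵢ², a [0, ∞) bound
on τ², relative tolerance 10⁻¹⁰ and at most 200 iterations, initialised at
the two-stage solution (so the optimality test ℓ_opt ≥ ℓ_plug-in is
structural). Fitting a 20-study meta-analysis takes ~5 ms.

**Kenward–Roger for a scalar effect.** With Φ = (1'V⁻¹1)⁻¹,
P_r = 1'(∂V⁻¹/∂θ_r)1, Q_rs = 1'(∂V⁻¹/∂θ_r)V(∂V⁻¹/∂θ_s)1 and W the inverse
information matrix of the variance parameters θ (V is linear in every θ, so
the second-derivative term vanishes):

    Φ_A = Φ + 2Φ² Σ_rs W_rs (Q_rs − Φ P_r P_s),
    df  = 2 / (Φ² Σ_rs W_rs P_r P_s) = 2Φ²/Var̂(Φ̂),

the general Kenward–Roger degrees of freedom collapsing to the
Satterthwaite form for a one-dimensional contrast (the accompanying scale
factor λ is identically 1 in the balanced case and is not applied to
intervals, matching standard mixed-model software). In the balanced
equal-v̂ case this gives Φ_A = S²/I and df = I − 1 exactly — the t interval
on the study estimates — which the tests assert. The information matrix is
**expected** for the two-stage fit (analytic, from the restricted
likelihood in τ²) and **observed** for the one-stage fit (central-difference
Hessian of the analytic gradient), the customary defaults for the
respective software routes; both are flag-selectable, and a non-positive
observed Hessian falls back to expected information with a warning. At very
small I the df can fall below 1 and is floored at 1 with a warning rather
than silently clamped elsewhere. Intervals use t quantiles with the
(generally non-integer) df.

## Synthetic data

The generator emulates a corpus of 1:1-randomised trials: study sizes
nᵢ = round(exp(Z)), Z ~ N(3.798, 1.104²) — a right-skewed distribution with
mean ≈ 82 patients, as observed in published trial collections — rounded
first and then floored at 20; per-study residual variances
σᵢ² = 50/χ²₅₀ (mean 50/48 ≈ 1.04, an independent scaled inverse-χ² draw per
study); study intercepts 0; true effect β = 0; random treatment effects
bᵢ ~ N(0, τ² = 1). Arms are split 1:1 with the extra patient allocated to
control when nᵢ is odd. All draws are pure functions of (config, seed).
What the generator does **not** emulate: covariates, unequal allocation,
missing data, non-Gaussian outcomes, correlations between study size and
effect (small-study effects), or random study intercepts — so passing tests
demonstrate procedure equivalence and calibration *under the stated
mechanism*, not robustness to those realities.

## Simulation study

For each study count I, `nsim` datasets are generated (replicate r uses
seed base + r, scenario offsets keep streams disjoint) and *both*
procedures are fitted to the same dataset; failures are recorded per
procedure and excluded pairwise, with a flag when they exceed 5% of a
scenario. Performance measures: mean bias of β̂ with MC SE s/√nsim;
empirical variance of the REML point estimates (independent of the KR
adjustment by construction) with MC SE var·√(2/(nsim−1)); coverage of the
nominal-95% KR t-intervals with binomial MC SE; and the relative precision
gain 100·(Var_emp(one-stage)/Var_emp(two-stage) − 1) with a leave-one-out
jackknife MC SE over the paired replicates. Default problem sizes follow
the generator (I up to 40, nsim = 1000 per scenario); the acceptance script
runs I = 20 and I = 10 at nsim = 1000, which takes a couple of minutes on
one CPU.

## Known limitations

* The small-sample variance formula is second-order; at nᵢ ≤ 6 the plug-in
  weights are so heavy-tailed that its expectation is infinite (the
  estimator remains finite and conservative in any realisation).
* The one-stage observed-information Hessian is numerical; at boundary
  solutions (τ̂² = 0 with very few studies) it can be indefinite, triggering
  the expected-information fallback.
* Aggregate-data inputs without per-study sample sizes cannot use the
  small-sample variance or common-variance pooling; these fail loudly
  rather than approximating.
* Only two-arm, 1:1-randomised, covariate-free Gaussian settings are
  supported; random study intercepts and multivariate second stages are out
  of scope.
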