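# Methods

## The problem

Two-arm randomized trials with a continuous outcome are commonly analysed
with a linear model

    y = α + γ z + β x + ε,     ε ~ N(0, σ_ε),

where `z` ∈ {0, 1} is the arm indicator, `γ` the treatment effect, and `x`
a baseline covariate believed to predict the outcome. Adjusting for `x`
sharpens the estimate of `γ`. In practice `x` is often *dichotomized* —
replaced by a two-level variable split at some threshold — before entering
the model, usually because the same split was used to stratify the
randomization. Dichotomization throws away within-group variation in `x`
and therefore gives back part of the precision that adjustment bought.

Medical covariates (BMI, weight, lipid panels, biomarker scores) are
frequently right-skewed, so this package models `x` as skew-normal,
`x ~ SN(φ, ω, λ)`, with density

    f(x) = (2/ω) φ((x−φ)/ω) Φ(λ(x−φ)/ω),

location `φ`, scale `ω` > 0, shape `λ` (λ = 0 recovers the normal; λ > 0
skews right). Its variance is σ_x² = ω² (1 − 2λ²/(π(1+λ²))).

## The three analysis models and D

With 1:1 allocation (n/2 per arm, S_zz = n/4), the sampling variance of
the treatment-effect estimator γ̂ has closed forms under three analyses:

| model                | covariate entered as | V(γ̂) |
|----------------------|----------------------|-------|
| full                 | raw x                | 4σ_ε²/n |
| restricted           | omitted              | 4(σ_ε² + β²σ_x²)/n |
| partially restricted | dichotomized x_d     | 4(σ_ε² + β²(σ_x² − V(x_d)))/n |

Here the dichotomized covariate x_d takes the conditional mean of x below
the threshold u on one side and above it on the other. That coding makes
x_d and the residual x − x_d uncorrelated, so the covariate variance
partitions exactly: σ_x² = V(x_d) + V(x − x_d). Any affine recoding of
x_d — including the 0/1 indicator the simulator uses — yields the identical
least-squares fit, because a single regressor's affine transform is
absorbed by its coefficient and the intercept.

V(x_d) follows from the truncated means of the skew-normal. For the
standard case, with truncation points a < b,

    E[X | a < X < b] = −(f(b) − f(a))/(F(b) − F(a))
                       + δ√(2/π) · (Φ(b s) − Φ(a s))/(F(b) − F(a)),

with s = √(1+λ²) and δ = λ/√(1+λ²). We carry the *signed* δ (rather than
√(λ²/(1+λ²))) so that left-skewed distributions mirror right-skewed ones;
the reflection identity D(−λ, 1−τ) = D(λ, τ) is verified in the tests.
Writing τ = F(u) for the percentile of the threshold,

    V(x_d) = ω²/(τ(1−τ)) · ( f(F⁻¹(τ)) + δ√(2/π) (τ − Φ(F⁻¹(τ)·s)) )².

The **dichotomization efficiency**

    D(λ, τ) = [V(γ̂; restricted) − V(γ̂; partial)] /
              [V(γ̂; restricted) − V(γ̂; full)]
            = V(x_d) / σ_x²   (standard case)

is the fraction of the full-adjustment precision gain retained after
dichotomizing. It depends only on (λ, τ): location and scale cancel
exactly, and β, σ_ε, n cancel in the ratio. For a normal covariate split
at the median, D = 2/π ≈ 0.637 — the classical result that a median split
keeps about 64% of the adjustment benefit.

Two independent routes to D are implemented and required to agree to 1e−6
in the tests: the single closed-form expression above, and the two-point
construction τ(u₋−μ)² + (1−τ)(u₊−μ)² assembled from the truncated means.

## Numerical choices

- **CDF.** No closed form exists; we use Owen's T function,
  F(z) = Φ(z) − 2T(z, λ) (`scipy.special.owens_t`), accurate to ~1e−15
  in the body of the distribution. Adaptive quadrature of the density is
  the independent oracle in the tests (agreement ≤ 1e−8). In the far tails
  Owen's T leaves noise at the 1e−16 level; the CDF is clipped to [0, 1].
- **Quantile.** Bracketed Brent root-finding on the monotone CDF, bracket
  seeded at the normal quantile shifted by the skew-normal mean and
  expanded as needed; round-trip tolerance 1e−8 in probability.
- **Truncated means.** Implemented for the standard case and generalized
  by x ↦ φ + ωx. An interval whose probability mass underflows double
  precision raises a degenerate-truncation error rather than returning a
  0/0 artifact.
- **Sampling.** The hidden-truncation construction
  X = δ|Z₀| + √(1−δ²) Z₁ with Z₀, Z₁ iid N(0,1), driven by
  `numpy.random.default_rng(seed)`; a seed is mandatory.
- **Percentile grid for cut-points.** Grid search at resolution 0.01 with
  two-decimal reporting, matching the granularity at which the optimum and
  the acceptable range are conventionally quoted. Ties within 1e−12
  resolve to the grid point closest to the median, which makes the
  symmetric λ = 0 case report exactly 0.5. Range boundaries use the strict
  inequality D > threshold; the λ = 0 row pins this down numerically
  (D(0.35) ≈ 0.603 > 0.6 > D(0.34) ≈ 0.598). A golden-section `refine`
  option polishes the argmax off-grid when wanted.
- **τ near 0 or 1.** τ(1−τ) appears in denominators; operations accept
  τ ∈ [1e−6, 1−1e−6] and raise outside it.

## The trial simulator

`generate_trial` draws a trial of n participants (first n/2 control,
second n/2 intervention — exactly balanced, matching S_zz = n/4), a
skew-normal covariate, and outcomes from the linear model. Defaults used
throughout the corroboration study: treatment effect γ = 15, covariate
slope β = 20, residual SD σ_ε = 30 (a standardized effect of 1/2), 100
participants per arm, 500 replicate trials per setting.

`fit_three_models` fits the three OLS regressions (statsmodels) and
returns the *model-based* variance of the treatment coefficient — the
squared standard error reported by each fit. The partial model thresholds
the covariate at the population quantile F⁻¹(τ), so the simulated τ is
exactly the analytic τ, and codes the split as a 0/1 indicator.

Because the per-replicate efficiency ratio has a noisy denominator,
`empirical_efficiency` estimates D by regressing the partial precision
gain V(restricted) − V(partial) on the full gain V(restricted) − V(full)
across replicates and taking the slope, with a t-based 95% CI. The
regression includes an intercept by default; a no-intercept variant is
available (`with_intercept=False`). Replicate r uses seed `seed + r`, and
grid cells in `simulation_study` use seed blocks offset by 10⁶, so any
subset reproduces independently and the whole study is bit-for-bit
reproducible from one master seed.

### What the simulator does and does not show

The generator realizes exactly the assumptions behind the closed forms:
a linear covariate–outcome relationship, homoskedastic normal residuals,
perfect 1:1 balance, and a covariate that is exactly skew-normal. Passing
tests therefore corroborate the algebra, not the robustness of the model
to real-data violations (non-linearity, heteroskedasticity, measurement
error, covariate–treatment interaction), which are outside this package's
scope.

At 100 per arm the model-based variances carry a small finite-sample bias
at extreme percentiles: with τ = 0.9 only ~20 participants fall in the
small group, and the replicate-mean gains give a ratio about 5% below the
asymptotic D (the bias disappears by ~500 per arm). With 500 replicates
the CI half-width (~0.045) is comparable to that bias, so confidence
intervals at extreme τ cover the asymptotic value slightly less often
than nominal. This is a property of the estimator at this trial size, not
of the closed forms; the corroboration test requires ≥ 90% of the 18
grid-cell CIs to cover, which holds with a one-cell margin.

## Fitting skew-normal parameters to percentile tables

Public summary data often come as percentile tables rather than
microdata. `fit_sn_to_percentiles` treats the tabulated values v₁ < … <
v_K as bin edges, the consecutive percentile gaps (with open tails) as
observed bin masses m_i, and maximizes the grouped multinomial
log-likelihood Σ m_i log(F(v_i; θ) − F(v_{i−1}; θ)) per unit observation
mass. This is a proper likelihood for exactly the data published; a
least-squares-on-CDF objective (`objective="cdf_lsq"`) is provided as a
sensitivity check, and on exact tables the two agree.

Optimization is Nelder–Mead with multi-start (shape seeds −5, 0, +5, a
quantile-skew moment start, and the fitted normal with shape 0); the
scale is parameterized on the log scale. The normal submodel (shape fixed
at 0) is fitted first with the same objective; since it is nested, the
skew-normal log-likelihood is never reported below it. Convergence
failures set `converged=False` with diagnostics instead of raising.
`compare_to_normal` reports both log-likelihoods, the likelihood-ratio
statistic 2(ℓ_SN − ℓ_N) on the per-unit-mass scale, and a qualitative fit
grade from the maximum |fitted CDF − tabulated percentile| (< 0.01
"excellent", < 0.05 "moderate", else "poor"). A 4-row table (3 parameters
+ 1 df) fits but is flagged low-information.

On noiseless 9-point tables generated from known parameters the fitter
recovers location and scale to well under 1% and the fitted CDF matches
the tabulated percentiles to < 1e−6; the tests require the looser
< 0.01 CDF deviation. Real percentile tables published by health agencies
carry rounding and sampling noise that these synthetic fixtures do not
emulate, so recovery there is necessarily coarser.

## Limitations

- Results are asymptotic in the trial size; at 100 per arm the simulator
  shows percent-level finite-sample deviations at extreme split
  percentiles (see above).
- Only two-level splits, 1:1 allocation and a linear covariate effect are
  covered; multi-bin stratification, unequal allocation and interactions
  are out of scope.
- The skew-normal family itself may fit real covariates imperfectly; the
  fitting module quantifies this via the CDF-deviation grade rather than
  assuming it away.
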