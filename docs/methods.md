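# Methods

## Model and hypotheses

All procedures assess a univariate i.i.d. sample X₁,…,Xₙ with continuous cdf
F against a hypothesized continuous model cdf F₀.  Deviations are confined
to the semiparametric family of Lehmann alternatives F = F₀^θ, θ > 0 — the
proportional-hazards model transplanted from survivor functions to cdfs.
"Good fit" is the *alternative* hypothesis

    K: 1/(1+ε) < θ < 1+ε,

tested against H: θ outside that interval.  Rejecting H therefore
establishes approximate fit with type-I-error control at level α: the
probability of *wrongly declaring fit* is at most α.  This is the defining
property of an equivalence test and the reverse of the classical
goodness-of-fit logic, where α controls the error of wrongly declaring
misfit.

### The margin and its two scales

For Lehmann alternatives the Kolmogorov distance has the closed form
‖F₀^θ − F₀‖ = |θ^{1/(1−θ)} − θ^{θ/(1−θ)}| (any continuous F₀; the supremum
is attained where F₀ = θ^{1/(1−θ)}).  Bounding it by δ is equivalent to the
θ-interval above, with ε solving

    (1+ε)^{−1/ε} − (1+ε)^{−(1+ε)/ε} = δ.

`margins` evaluates the left side as exp(−a·log1p(ε)) for numerical
stability and inverts it by Brent's method on an adaptively doubled
bracket (tolerance 1e−12 on ε); the map is strictly increasing, so the root
is unique.  Default margin in examples: δ = 0.15 ↔ ε = 0.5077, a moderate
tolerance comparable to customary equivalence-margin choices.

## Exact UMP test (fully specified F₀)

By the probability-integral transform, −log F₀(Xᵢ) is exponential with rate
θ, so S = Σᵢ −log F₀(Xᵢ) ~ Gamma(n, 1/θ) and the ML estimator θ̂ₙ = n/S has
exact cdf t ↦ 1 − G₂ₙ(2θn/t) with G₂ₙ the chi-square(2n) cdf — free of F₀.
The sample enters only through S, the sufficient statistic of a
one-parameter exponential family, which guarantees a uniformly most
powerful level-α test of H vs K: reject iff C₁ < θ̂ₙ < C₂ where (C₁, C₂)
give rejection probability exactly α at both θ = 1/(1+ε) and θ = 1+ε.
Strict inequalities are used at the constants (a measure-zero event).

### Solving for the critical constants

On the scale v₁ = 2n/C₂ < v₂ = 2n/C₁ the two conditions read
G(θ_b·v₂) − G(θ_b·v₁) = α at both boundary values θ_b.  For moderate-to-
large n the conditions decouple: at the solution each equation involves one
chi-square tail that is far below machine precision, so a nested 1-D solve
(fix C₁, solve one equation for C₂, iterate on C₁) sees a flat plateau and
can return a spurious root.  The implementation instead

1. runs 8 Gauss–Seidel sweeps, alternately solving each equation *exactly*
   in one variable through the chi-square ppf (this converges immediately
   in the decoupled regime and lands near the solution otherwise), then
2. polishes with a damped 2-D Newton iteration whose Jacobian uses the
   analytic chi-square pdf, halving steps until both residuals shrink.

The achieved residual is stored on the result and a hard cap of 1e−9 turns
non-convergence into an error rather than unverified constants.  The solver
was exercised over n ∈ [1, 10⁴], α ∈ [0.001, 0.49], ε ∈ [0.01, 20] with
residuals ≤ 1e−13 throughout.

Power against any θ is the closed form G₂ₙ(2θn/C₁) − G₂ₙ(2θn/C₂); the
smallest n achieving a target power is found by doubling plus integer
bisection (power is monotone in n at fixed margin).

## Grouped-data counterpart

The support of F₀ is cut at its j/k-quantiles, j = 1..k−1, giving k classes
of model probability 1/k (π° = (1/k,…,1/k)).  Under F₀^θ the class masses
are πⱼ(θ) = F₀(bⱼ)^θ − F₀(bⱼ₋₁)^θ; since the boundary cdf values are j/k
regardless of F₀, the induced Euclidean margin
ε\* = ‖π(1+ε) − π°‖₂ depends only on (k, ε) — for k = 5, ε = 0.5077 it is
0.1548.  The multinomial equivalence test rejects its null
d(π, π°) ≥ ε\* iff

    d²(π̂, π°) < ε\*² − z₁₋α·vₙ/√n,
    vₙ² = 4[Σⱼ aⱼ²π̂ⱼ − (Σⱼ aⱼπ̂ⱼ)²],   aⱼ = π̂ⱼ − π°ⱼ,

with π̂ the relative class frequencies.  The variance is computed in this
moment form, algebraically identical to the ratio/double-sum form but
defined also when a class is empty.  When vₙ = 0 (e.g. π̂ = π° exactly) the
bound is taken at its limit ε\*² and the result flagged degenerate; the
perfectly uniform count vector then rejects, which is the continuity-
consistent reading of the rule.  Raw data are tabulated with the
left-open/right-closed convention (bⱼ₋₁, bⱼ].

Exact power enumerates all count compositions of n into k classes (guarded
at 2·10⁷ compositions) and sums multinomial probabilities over the
rejection region; Monte-Carlo power simulates multinomial draws.  Both
paths decide each count vector through the same vectorized kernel as the
single-sample test, so there is one source of truth for the rejection
region.  Matched comparisons (k = 5, ε\* = 0.1548 vs ε = 0.5077) show the
grouped test clearly below the exact UMP power — grouping wastes
information here just as it does in lack-of-fit testing.

## Location-scale families: TOST score test

For the composite model {F₀((·−μ)/σ): μ ∈ ℝ, σ > 0} with Lehmann exponent θ
the log-likelihood is

    l = n log θ + (θ−1) Σ log F₀(zᵢ) + Σ log[(1/σ) f₀(zᵢ)],  zᵢ = (xᵢ−μ)/σ.

A global MLE of θ is unreliable in this model (the likelihood often fails
to attain an interior maximum), so each one-sided boundary hypothesis is
tested with the efficient score: at fixed boundary θ_b the nuisance
parameters are profiled out by the restricted MLE (μ̃, σ̃) solving
∂l/∂μ = ∂l/∂σ = 0, and U(θ_b) = ∂l/∂θ at (θ_b, μ̃, σ̃).  The TOST decision
rejects lack of fit iff U(θ₁)/ṽ_l > z₁₋α **and** U(θ₂)/ṽ_r < z_α, with
θ₁ = 1/(1+ε), θ₂ = 1+ε.

### Variance convention

ṽ² = n·ĩ(θ_b), where ĩ = 1/(V⁻¹)₁₁ is the per-observation *partial*
information for θ and V the expected covariance matrix of the
per-observation score contributions (∂θ, ∂μ, ∂σ) under the law
F₀((·−μ)/σ)^θ_b.  Using the expected rather than observed information
avoids the known inconsistency of nuisance-parameter score tests with
estimated variance.  Because the score vector transforms as
diag(1, 1/σ, 1/σ) under location-scale changes, ĩ — hence ṽ — depends only
on (θ_b, F₀), not on the fitted (μ̃, σ̃): for the normal family at n = 100,
ε = 0.5077 the two boundary variances are ṽ_l² = 1.636889 and
ṽ_r² = 0.276968 to six decimals, reproducible without any data.

### Numerics

- **Restricted MLE**: Newton–Raphson on the two nuisance score equations,
  initialized at the sample mean and uncorrected standard deviation,
  finite-difference Jacobian of the analytic scores, step halving (≤ 30)
  with σ > 0 enforced by rejection, convergence when the largest score
  component is below 1e−8·n, cap 50 iterations with a hard error (no
  unconverged fit is ever returned).  Cross-checked against Nelder–Mead
  maximization of the likelihood itself.
- **Expected information**: no closed form exists; V is integrated on the
  uniform scale w = F(x) (so the integrand is evaluated at
  z = F₀⁻¹(w^{1/θ})) with 64-node Gauss–Legendre rules on panels refined
  geometrically toward both endpoints, taming the logarithmic singularity
  of log F₀ at w → 0.  A node-doubling self-check (64 → 128) must move no
  matrix entry by more than 1e−8 or an error is raised.  f₀′/f₀ is supplied
  analytically for the catalogue models and by central differences for
  user-supplied ones.

Monte-Carlo studies of the TOST at perfect fit (θ = 1, normal family,
ε = 0.5077) confirm that its power is still far below 50% at n = 500 —
establishing fit of a distributional *shape* with honest error control
needs thousands of observations, which is the procedure's practical
limitation rather than a defect of the implementation.

## Synthetic data and what the tests show

The generator draws X = F₀⁻¹(U^{1/θ}) with U uniform on the open unit
interval, which *is* the model — there is no approximation gap.  The
regenerated worked-example sample (n = 100, θ = 1, standard normal, fixed
seed) mirrors the design of the published illustration: n = 100 draws from
a perfectly fitting model, analyzed once with F₀ fully specified (fit
established) and once as a location-scale family (fit not establishable at
this n).  Because the generator produces exactly Lehmann data, passing
tests validate the distribution theory and the algorithms; they say
nothing about robustness to data that violate the semiparametric form
F = F₀^θ, which the method does not claim.

Test problem sizes were chosen to keep the full suite fast while leaving
Monte-Carlo error well below the asserted tolerances: 10⁵ replicates for
boundary-size checks (3 binomial SEs ≈ 0.002), 10⁴ for power comparisons,
10⁶ draws for score-covariance cross-checks, 2000 replicates for the
n = 500 TOST power study.

## Known limitations

- Only the Lehmann (proportional-hazards-type) indifference zone is
  supported; margins in other metrics (Cramér–von Mises, total variation)
  are out of scope.
- No censoring; the survival-analysis connection is conceptual only.
- The grouped test and the score test are asymptotic (the score test warns
  below n = 10 by refusing to run); only the fully-specified-F₀ UMP test is
  exact at every n.
- The score test covers location-scale families only, with the shape F₀
  fixed.
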