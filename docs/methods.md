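# Methods

## Model

A p×n random matrix Y follows the matrix-variate mean-mixture-of-normal
(MVMMN) law when it admits the stochastic representation

    Y = M + W·Λ + X,   X ~ N_{p,n}(0, Σ, Ψ),   W ~ h(w) independent of X,

with location M, skewness Λ (both p×n), symmetric positive-definite row
scale Σ (p×p) and column scale Ψ (n×n), and a positive scalar mixing
variable W. The mixing variable perturbs only the mean — in contrast with
mean–variance mixtures (e.g. the normal inverse-Gaussian family), where W
also scales the covariance. Conditionally on W = w the law is matrix
normal at M + wΛ, so the density is a one-dimensional integral of the
matrix-normal density against h. Vectorizing, `vec(Y)` follows the
pn-dimensional mean-mixture law with scale Ψ ⊗ Σ; this dense
representation is used only as a test oracle.

Three mixing laws admit closed forms. All of them factor through two scalar
statistics of an observation,

    t  = tr(Ψ⁻¹ Λᵀ Σ⁻¹ (Y − M)),      η² = tr(Ψ⁻¹ Λᵀ Σ⁻¹ Λ) + 1:

* **rsn** — W ~ TN(0,1;(0,∞)) gives the restricted matrix-variate
  skew-normal; density `(2/η) exp(A²/2) φ(Y) Φ(A)` with `A = t/η`.
* **exp1** — W ~ Exp(1) gives `(√(2π)/η₁*) exp(A₁*²/2) φ(Y) Φ(A₁*)` with
  `η₁*² = η² − 1`, `A₁* = (t−1)/η₁*`. (A published rendering of the
  normalizing constant reads `2π η₁*`; completing the square in the
  mixture integral gives `√(2π)/η₁*`, and the quadrature oracle confirms
  it — the package implements the re-derived constant.)
* **weib21** — W ~ Weibull(2,1), i.e. h(w) = 2w·exp(−w²), gives
  `(2√(2π)/η₂*²) exp(A₂*²/2) φ(Y) (A₂*Φ(A₂*) + φ(A₂*))` with
  `η₂*² = η² + 1`, `A₂* = t/η₂*`. The constants force this Weibull
  parameterization; a scale-inside variant would change η₂*.

Here φ(Y) is the matrix-normal density at (M, Σ, Ψ) and Φ, φ the standard
normal cdf/pdf. Posterior mixing moments are truncated-normal: W|Y is
TN(A/η, 1/η²) under rsn, TN(A₁*/η₁*, 1/η₁*²) under exp1, and a
length-biased truncated normal under weib21, with
`E(Wʳ|Y) = η₂*Φ(A₂*)/(A₂*Φ(A₂*)+φ(A₂*)) · E(V^{r+1})`,
V ~ TN(A₂*/η₂*, 1/η₂*²). Custom mixing laws are supported through
quadrature only.

## Numerical choices

* **No explicit inverses.** Mahalanobis terms and the skew statistics go
  through Cholesky factors and triangular solves; densities use
  log-determinants from the factors.
* **Log-space Gaussian factors.** Every Φ enters through `log Φ` via the
  complementary error function. The combinations `A²/2 + log Φ(A)` that
  appear in all three densities cancel catastrophically for A ≪ 0; they
  are evaluated exactly as `log(erfcx(−A/√2)/2)`, finite for any A.
* **Truncated-normal moments.** The two-term recursion
  `E(Wʳ) = μE(Wʳ⁻¹) + (r−1)σ²E(Wʳ⁻²)` is used for μ/σ > −30; beyond that
  the recursion cancels (the moments scale like (σ/|a|)ʳ while its terms
  are O(σʳ)) and the moments are computed by 80-node Gauss–Laguerre
  quadrature in the exponentially tilted variable, accurate to ~1e−10.
  Mills ratios always go through `erfcx`.
* **Quadrature oracle.** The numeric density integrates the matrix-normal
  slice against h with the integrand rescaled by its grid maximum and the
  adaptive rule split at the peak; it serves as the independent oracle for
  every closed form (agreement < 1e−7 over random instances is enforced in
  the acceptance tests).

## Estimation

The ECM algorithm treats the mixing draws as latent. Per iteration:

1. **E-step.** `ŵᵢ = E(W|Yᵢ)`, `t̂ᵢ = E(W²|Yᵢ)` from the closed-form
   posteriors, vectorized across observations.
2. **CM-step 1 (location/skewness).**
   `Λ̂ = [mean(ŵᵢYᵢ) − w̄·Ȳ]/(t̄ − w̄²)`, then `M̂ = Ȳ − w̄·Λ̂`. The pair
   solves the joint stationarity system of the Q-function, so the step is
   an exact joint maximization and the observed log-likelihood is
   non-decreasing (a variant that plugs the previous skewness iterate into
   the location update has the same fixed points but no ascent guarantee;
   it is available as an option and not used by default).
3. **CM-step 2 (scales).** Σ̂ in closed form given the current Ψ, then Ψ̂
   given the fresh Σ̂; both symmetrized, with a tiny escalating diagonal
   jitter if a Cholesky fails (rare, logged as a warning).

**Scale identification.** The likelihood is exactly invariant under
(Σ, Ψ) → (cΣ, Ψ/c), and the entire ECM trajectory is equivariant under
this rescaling — the converged split is proportional to the starting
split and carries no information. The package pins the convention
**tr(Ψ̂) = n** (average unit column variance), applied every iteration;
the log-likelihood, AIC/BIC and all posterior quantities are unaffected.
The convention coincides with the true column scales of the simulation
designs used for validation (unit diagonal / identity).

**Initialization.** The location starts at the sample mean and the
skewness at the all-ones matrix; the scales start diagonal with per-row
and per-column sums of squared deviations from the grand row/column means
as profiles (`initialize()` returns exactly this seed). Two repairs are
applied inside `fit()`:

* the *product* of the seed scales is rescaled so that
  `tr(Σ⁰)·tr(Ψ⁰) = Σⱼₗ Var(Yⱼₗ)` — the matrix-normal moment identity.
  Without this each factor carries the full data variance, the product is
  ~N² too large, the skew statistic underflows, and the iteration can fall
  into the absorbing Λ = 0 fixed point (every EM iteration from Λ = 0
  keeps Λ = 0, for any family);
* the iteration self-reinforces the sign of the starting skewness, so the
  default start burns in 30 iterations from both Λ⁰ = +1 and Λ⁰ = −1 and
  continues the branch with the higher log-likelihood. The fit is still
  fully deterministic.

**Stopping.** Default is Aitken acceleration: with
`a = (ℓₖ₊₁−ℓₖ)/(ℓₖ−ℓₖ₋₁)`, the asymptotic estimate
`ℓ∞ = ℓₖ₊₁ + (ℓₖ₊₁−ℓₖ)/(1−a)` is compared with ℓₖ and iteration stops
when the gap drops below the tolerance (default 1e−5); if the acceleration
factor leaves (0,1) the plain likelihood difference is used for that
iteration. Plain likelihood-difference and parameter-difference rules are
available. Maximum 2000 iterations.

**Model selection.** `m = 2pn + p(p+1)/2 + n(n+1)/2` free parameters
(the non-identified Kronecker scale factor is *not* subtracted — this
convention matches the published satellite-fit AIC/BIC arithmetic, m = 127
at p = 4, n = 9); AIC = 2m − 2ℓ, BIC = m·log N − 2ℓ.

## Synthetic-data generator

The benchmark generator is the matrix-variate normal inverse-Gaussian
(MVNIG) law, a normal *mean–variance* mixture
`Y = M + WΛ + √W·X` with W ~ GIG(−0.5, χ, ψ) — inverse Gaussian with mean
√(χ/ψ) and shape χ. Defaults follow the published study conditions:
χ = ψ = 3 (so E W = 1, Var W = 1/3), the fixed 3×4 location/skewness and
unit-diagonal scale matrices of the benchmark design, N ∈ {50…2000}, 200
replications for model comparison and estimation-error studies, 1000 for
the consistency study (tests and the acceptance script use 200 at N = 100
and 25 replications for the N = 2000 / N = 500 studies, which this
package treats as its standard reduced profiles). Because W multiplies
both the mean shift and the covariance, the generator lies *outside* the
fitted family: the studies measure how the three misspecified candidates
rank, not parameter recovery of a well-specified model. The AR(1) variant
(`ar1_spec`) builds Λ = [λ^|i−j|] (3×4) and Σ = [ρ^|i−j|] + 0.001·I (3×3)
with Ψ = I₄ and zero location.

What the generator does not emulate about real three-way data: per-entry
heteroscedasticity beyond the Kronecker structure, discreteness and
clipping of intensity data, spatial nonstationarity, and dependence
between observations. Passing benchmarks therefore validates the
estimator's internal consistency and its behavior under the published
simulation conditions, not robustness to arbitrary real-world deviations.

## Known limitations

* No standard errors or confidence intervals for the estimates (the
  observed-information machinery is out of scope).
* Closed forms exist only for the three named mixing laws; custom laws run
  through quadrature and cannot be fitted by the ECM.
* The Λ = 0 point is an EM fixed point for every family; the dual-sign
  start resolves the generic sign ambiguity but a pathological dataset
  could still require user-supplied starting values.
* The Kronecker split reported for Σ̂ and Ψ̂ is a convention (tr Ψ̂ = n);
  any comparison of scale estimates across software must account for the
  respective conventions.
* Quadratic-form decomposition is a Monte-Carlo verification utility; no
  exact non-central Wishart densities are provided.
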