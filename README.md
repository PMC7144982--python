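# mvmmn — matrix-variate mean-mixture-of-normal distributions

`mvmmn` models collections of **matrix-valued observations** — three-way
data such as multi-band pixel neighborhoods in satellite images, repeated
multivariate measurements, or short multivariate time series — with a family
of *skewed* matrix distributions, and fits them by maximum likelihood.

## The model

A random p×n matrix **Y** follows the matrix-variate mean-mixture-of-normal
(MVMMN) law when

```
Y = M + W·Λ + X,      X ~ N_{p,n}(0, Σ, Ψ),   W ~ h(w) ≥ 0 independent of X
```

where **M** is the location, **Λ** the skewness matrix, **Σ** (p×p) and
**Ψ** (n×n) the row and column scale matrices (Kronecker-structured
covariance: `cov(vec Y | W) = Ψ ⊗ Σ`), and *W* a positive scalar mixing
variable that shifts only the mean. Three mixing laws give closed-form
densities, all driven by two scalar statistics
`t = tr(Ψ⁻¹Λᵀ Σ⁻¹(Y−M))` and `η² = tr(Ψ⁻¹Λᵀ Σ⁻¹Λ) + 1`:

| family   | W ~                      | resulting law                          |
|----------|--------------------------|----------------------------------------|
| `rsn`    | TN(0, 1; (0, ∞))         | restricted matrix-variate skew-normal (RMVSN) |
| `exp1`   | Exponential(mean 1)      | exponentiated MVMMN (MVMMNE)           |
| `weib21` | Weibull(shape 2, scale 1)| mixed-Weibull MVMMN (MVMMNW)           |

Parameters are estimated by an **ECM algorithm**: the E-step needs only the
posterior moments `E(W|Yᵢ)`, `E(W²|Yᵢ)` (truncated-normal closed forms),
and the CM-steps update (M, Λ) and (Σ, Ψ) in closed form. Convergence is
monitored by Aitken acceleration; competing families are ranked by AIC/BIC.

The package also provides the distribution calculus (mean, characteristic
function, second moments, transposition, affine maps, marginals,
conditionals, quadratic forms), exact samplers, and the simulation
benchmarks used to validate the estimator.

## Worked example

```python
import numpy as np
from mvmmn import MatrixMMN, example1_spec, sample_mvnig

# 500 skewed, heavy-tailed 3x4 matrices from the normal inverse-Gaussian
# benchmark generator (not itself a member of the fitted family)
data = sample_mvnig(example1_spec(), N=500, seed=7)

result = MatrixMMN(data, family="exp1").fit()
print(result.summary())
```

prints (abridged):

```
Matrix mean-mixture of normal — ECM maximum likelihood
==========================================================
model:          MVMMNE (exp1 mixing)
observations:   N = 500, matrix shape 3 x 4
log-likelihood: -7686.2571
free params:    m = 40
AIC:            15452.5142
BIC:            15621.0986
iterations:     301 (converged: True)
```

`m = 40 = 2pn + p(p+1)/2 + n(n+1)/2` counts the free parameters (location,
skewness, both scale triangles). Comparing all three candidates,

```python
from mvmmn import compare_families
print(compare_families(data))
```

```
             loglik   m           aic           bic  converged  n_iter
family
rsn    -7696.043377  40  15472.086753  15640.671077       True     170
exp1   -7686.257117  40  15452.514234  15621.098558       True     301
weib21 -7722.215120  40  15524.430239  15693.014563       True     132
```

the exponential-mixing model attains the smallest AIC/BIC, i.e. it absorbs
the generator's skewness and excess kurtosis best — the same ranking the
large-scale replication study produces.

A command-line interface mirrors the library (`mvmmn fit`, `mvmmn simulate`,
`mvmmn compare`, `mvmmn landsat`); `mvmmn landsat` reads the plain-text
Statlog satellite format (36 spectral attributes per line, reshaped to
4×9 band-by-pixel matrices) and fits the three candidates per land-cover
class.

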