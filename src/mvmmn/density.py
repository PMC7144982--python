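"""Densities, samplers and posterior mixing moments of the MVMMN family.

The matrix normal density is

    phi(Y; M, Sigma, Psi) = (2 pi)^(-np/2) |Sigma|^(-n/2) |Psi|^(-p/2)
                            etr{ -1/2 Sigma^-1 (Y-M) Psi^-1 (Y-M)^T },

and the mean-mixture law integrates it against the mixing density h:

    f(Y) = int phi(Y; M + w Lambda, Sigma, Psi) h(w) dw.

For the three named mixing families the integral has a closed form driven by
two scalar summaries of (Y, M, Lambda, Sigma, Psi):

    t   = tr(Psi^-1 Lambda^T Sigma^-1 (Y - M))
    eta^2 = tr(Psi^-1 Lambda^T Sigma^-1 Lambda) + 1

All Gaussian cdf factors are evaluated in log space (via the complementary
error function), so the closed forms stay finite far into the tails.  All
Mahalanobis terms use triangular solves against Cholesky factors; no scale
matrix is ever inverted explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, linalg, special

from .dataset import MatrixDataset
from .mixing import MixingLaw, mills_inverse, truncnorm_moments
from .params import MMNParams

__all__ = [
    "SkewSummaries",
    "matnorm_logpdf",
    "skew_summaries",
    "mmn_logpdf",
    "mmn_logpdf_numeric",
    "mmn_sample",
    "posterior_w_moments",
    "QuadratureError",
]

_LOG_2PI = math.log(2.0 * math.pi)
_LOG_SQRT_2PI = 0.5 * _LOG_2PI


class QuadratureError(RuntimeError):
    """Raised when the numeric density integral fails to converge."""


def _chol(mat: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(np.asarray(mat, dtype=float))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"{name} is not symmetric positive definite (Cholesky failed)"
        ) from err


def _logdet_from_chol(L: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def matnorm_logpdf(Y, M, Sigma, Psi) -> float:
    """Log-density of the matrix normal N_{p,n}(M, Sigma, Psi) at Y."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if Y.shape != M.shape:
        raise ValueError(f"Y has shape {Y.shape} but M has shape {M.shape}")
    p, n = Y.shape
    L_s = _chol(Sigma, "Sigma")
    L_p = _chol(Psi, "Psi")
    E = Y - M
    # tr(Sigma^-1 E Psi^-1 E^T) = || L_s^-1 E L_p^-T ||_F^2
    A = linalg.solve_triangular(L_s, E, lower=True)
    B = linalg.solve_triangular(L_p, A.T, lower=True)
    mahal = float(np.sum(B * B))
    return (
        -0.5 * n * p * _LOG_2PI
        - 0.5 * n * _logdet_from_chol(L_s)
        - 0.5 * p * _logdet_from_chol(L_p)
        - 0.5 * mahal
    )


@dataclass(frozen=True)
class SkewSummaries:
    """Scalar trace statistics through which every closed form factors.

    ``t_stat``  tr(Psi^-1 Lambda^T Sigma^-1 (Y-M));
    ``mahal``   tr(Sigma^-1 (Y-M) Psi^-1 (Y-M)^T);
    ``eta2``    tr(Psi^-1 Lambda^T Sigma^-1 Lambda) + 1  (= eta^2 >= 1);
    ``A``       t_stat / eta;
    ``eta1s2``  eta^2 - 1  (= eta_1*^2, may be 0 when Lambda = 0);
    ``A1s``     (t_stat - 1)/eta_1*, NaN (with ``a1s_defined=False``) at
                eta_1* = 0;
    ``eta2s2``  eta^2 + 1  (= eta_2*^2);
    ``A2s``     t_stat / eta_2*.
    """

    t_stat: float
    mahal: float
    eta2: float
    A: float
    eta1s2: float
    A1s: float
    eta2s2: float
    A2s: float
    a1s_defined: bool = True


def _param_factors(params: MMNParams):
    """Cholesky factors and the whitened skew matrix G = Sigma^-1 Lambda Psi^-1."""
    L_s = _chol(params.Sigma, "Sigma")
    L_p = _chol(params.Psi, "Psi")
    # G = Sigma^-1 Lambda Psi^-1 by two symmetric triangular solve pairs
    T = linalg.cho_solve((L_s, True), params.Lambda)
    G = linalg.cho_solve((L_p, True), T.T).T
    eta2 = float(np.sum(G * params.Lambda)) + 1.0
    return L_s, L_p, G, eta2


def skew_summaries(Y, params: MMNParams) -> SkewSummaries:
    """Compute the scalar summaries of one observation under ``params``."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape != (params.p, params.n):
        raise ValueError(
            f"Y has shape {Y.shape}, expected ({params.p}, {params.n})"
        )
    L_s, L_p, G, eta2 = _param_factors(params)
    E = Y - params.M
    A_ = linalg.solve_triangular(L_s, E, lower=True)
    B_ = linalg.solve_triangular(L_p, A_.T, lower=True)
    mahal = float(np.sum(B_ * B_))
    t_stat = float(np.sum(G * E))
    eta = math.sqrt(eta2)
    eta1s2 = eta2 - 1.0
    eta2s2 = eta2 + 1.0
    if eta1s2 > 0:
        a1s = (t_stat - 1.0) / math.sqrt(eta1s2)
        defined = True
    else:
        a1s = math.nan
        defined = False
    return SkewSummaries(
        t_stat=t_stat,
        mahal=mahal,
        eta2=eta2,
        A=t_stat / eta,
        eta1s2=eta1s2,
        A1s=a1s,
        eta2s2=eta2s2,
        A2s=t_stat / math.sqrt(eta2s2),
        a1s_defined=defined,
    )


# ---------------------------------------------------------------------------
# batch machinery shared with the ECM fitter


def _base_logpdf_batch(Ys: np.ndarray, params: MMNParams):
    """Matrix-normal log-densities and skew statistics for an (N,p,n) stack.

    Returns ``(base, t, eta2)`` where ``base[i]`` is the matrix normal
    log-density at ``Ys[i]`` and ``t[i]`` the skew trace statistic.
    """
    N, p, n = Ys.shape
    L_s, L_p, G, eta2 = _param_factors(params)
    E = Ys - params.M  # (N, p, n)
    # whiten rows: L_s^-1 E_i  for all i at once
    flat = E.transpose(1, 0, 2).reshape(p, N * n)
    A = linalg.solve_triangular(L_s, flat, lower=True).reshape(p, N, n)
    # whiten columns: (L_p^-1 (L_s^-1 E_i)^T)
    flat2 = A.transpose(2, 1, 0).reshape(n, N * p)
    B = linalg.solve_triangular(L_p, flat2, lower=True).reshape(n, N, p)
    mahal = np.einsum("nip,nip->i", B, B)
    t = np.einsum("pn,ipn->i", G, E)
    const = (
        -0.5 * n * p * _LOG_2PI
        - 0.5 * n * _logdet_from_chol(L_s)
        - 0.5 * p * _logdet_from_chol(L_p)
    )
    return const - 0.5 * mahal, t, eta2


def _log_ndtr_plus_half_sq(a):
    """a^2/2 + log Phi(a), stable for any real a.

    For a << 0 the two terms cancel to ~log(1/|a|) while each is O(a^2);
    the identity Phi(a) = erfcx(-a/sqrt(2)) exp(-a^2/2) / 2 removes the
    cancellation exactly.
    """
    a = np.asarray(a, dtype=float)
    small = np.minimum(a, 8.0)
    neg = np.log(0.5 * special.erfcx(-small / math.sqrt(2.0)))
    pos = 0.5 * a**2 + special.log_ndtr(a)
    return np.where(a < 8.0, neg, pos)


def _log_weib_factor_plus_half_sq(a):
    """a^2/2 + log( a*Phi(a) + phi(a) ), stable for any real a.

    Since a + phi(a)/Phi(a) > 0 always, the factor is written as
    Phi(a) * (a + mills_inverse(a)) and combined with the stable
    a^2/2 + log Phi(a) form.
    """
    a = np.asarray(a, dtype=float)
    return _log_ndtr_plus_half_sq(a) + np.log(a + mills_inverse(a))


def _mmn_logpdf_batch(Ys: np.ndarray, params: MMNParams) -> np.ndarray:
    """Closed-form log-density for each observation in an (N,p,n) stack."""
    family = params.mixing.family
    base, t, eta2 = _base_logpdf_batch(Ys, params)
    if family == "rsn":
        eta = math.sqrt(eta2)
        A = t / eta
        return math.log(2.0) - math.log(eta) + base + _log_ndtr_plus_half_sq(A)
    if family == "exp1":
        eta1s2 = eta2 - 1.0
        if eta1s2 <= 1e-14:
            warnings.warn(
                "exponential mixing with Lambda = 0 degenerates to the matrix "
                "normal density",
                RuntimeWarning,
                stacklevel=3,
            )
            return base
        eta1s = math.sqrt(eta1s2)
        A1 = (t - 1.0) / eta1s
        return (
            _LOG_SQRT_2PI - math.log(eta1s) + base + _log_ndtr_plus_half_sq(A1)
        )
    if family == "weib21":
        eta2s2 = eta2 + 1.0
        A2 = t / math.sqrt(eta2s2)
        return (
            math.log(2.0)
            + _LOG_SQRT_2PI
            - math.log(eta2s2)
            + base
            + _log_weib_factor_plus_half_sq(A2)
        )
    raise ValueError(
        f"no closed-form density for mixing family {family!r}; "
        "use mmn_logpdf_numeric"
    )


def mmn_logpdf(Y, params: MMNParams) -> float:
    """Closed-form log-density of the MVMMN law at one observation.

    Supports the three named mixing families; any other family dispatches to
    :func:`mmn_logpdf_numeric`.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape != (params.p, params.n):
        raise ValueError(
            f"Y has shape {Y.shape}, expected ({params.p}, {params.n})"
        )
    if not params.mixing.is_named:
        return mmn_logpdf_numeric(Y, params)
    return float(_mmn_logpdf_batch(Y[None], params)[0])


def mmn_logpdf_numeric(Y, params: MMNParams, tol: float = 1e-10) -> float:
    """Log-density by adaptive quadrature of the mixture integral.

    Serves as the independent oracle for the closed forms and as the only
    density route for custom mixing laws.  The integrand is rescaled by its
    maximum over a coarse grid before quadrature so the integral stays
    well-conditioned for extreme observations.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mix = params.mixing
    if mix.family == "point":
        (c,) = mix.nu
        return matnorm_logpdf(Y, params.M + c * params.Lambda, params.Sigma, params.Psi)

    lo, hi = mix.support
    lo = max(lo, 0.0) if lo == 0.0 else lo

    def log_integrand(w):
        return matnorm_logpdf(
            Y, params.M + w * params.Lambda, params.Sigma, params.Psi
        ) + np.log(max(float(mix.pdf(w)), 1e-300))

    grid_hi = hi if np.isfinite(hi) else max(30.0, lo + 30.0)
    grid = np.linspace(lo + 1e-9, grid_hi, 241)
    log_vals = np.array([log_integrand(w) for w in grid])
    shift = float(np.max(log_vals))
    w_peak = float(grid[int(np.argmax(log_vals))])

    def integrand(w):
        h = float(mix.pdf(w))
        if h <= 0.0:
            return 0.0
        return math.exp(
            matnorm_logpdf(Y, params.M + w * params.Lambda, params.Sigma, params.Psi)
            - shift
        ) * h

    # split at the integrand peak so the adaptive rule resolves narrow modes
    if lo < w_peak < (hi if np.isfinite(hi) else grid_hi):
        v1, e1 = integrate.quad(
            integrand, lo, w_peak, epsabs=tol, epsrel=1e-10, limit=400
        )
        v2, e2 = integrate.quad(
            integrand, w_peak, hi, epsabs=tol, epsrel=1e-10, limit=400
        )
        val, err = v1 + v2, e1 + e2
    else:
        val, err = integrate.quad(
            integrand, lo, hi, epsabs=tol, epsrel=1e-10, limit=400
        )
    if val <= 0.0 or err > max(tol * 10.0, abs(val) * 1e-6):
        raise QuadratureError(
            f"mixture quadrature did not converge (value={val:.3e}, "
            f"achieved tolerance={err:.3e})"
        )
    return shift + math.log(val)


def mmn_sample(params: MMNParams, N: int, seed=None) -> MatrixDataset:
    """Draw ``N`` observations via the hierarchy W ~ h, Y|W matrix normal.

    The matrix normal part is generated as ``L_Sigma Z L_Psi^T`` with lower
    Cholesky factors; any square root of the scales yields the same law.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(params.mixing.rvs(N, rng), dtype=float)
    L_s = _chol(params.Sigma, "Sigma")
    L_p = _chol(params.Psi, "Psi")
    Z = rng.standard_normal((N, params.p, params.n))
    X = np.einsum("pq,iqr,nr->ipn", L_s, Z, L_p)
    Ys = params.M[None] + w[:, None, None] * params.Lambda[None] + X
    return MatrixDataset(Ys)


# ---------------------------------------------------------------------------
# posterior moments of the mixing variable


def _posterior_moments_batch(t: np.ndarray, eta2: float, mixing: MixingLaw):
    """E(W|Y) and E(W^2|Y) from the skew statistics, vectorized over t."""
    family = mixing.family
    t = np.asarray(t, dtype=float)
    if family == "rsn":
        # W|Y ~ TN(A/eta, 1/eta^2)
        mom = truncnorm_moments(t / eta2, 1.0 / math.sqrt(eta2), 2)
        return mom[0], mom[1]
    if family == "exp1":
        eta1s2 = eta2 - 1.0
        if eta1s2 <= 1e-14:
            warnings.warn(
                "exponential mixing with Lambda = 0: Y carries no information "
                "on W; returning the prior moments (1, 2)",
                RuntimeWarning,
                stacklevel=3,
            )
            return np.full_like(t, 1.0), np.full_like(t, 2.0)
        # W|Y ~ TN(A1*/eta1*, 1/eta1*^2)
        mom = truncnorm_moments((t - 1.0) / eta1s2, 1.0 / math.sqrt(eta1s2), 2)
        return mom[0], mom[1]
    if family == "weib21":
        eta2s2 = eta2 + 1.0
        eta2s = math.sqrt(eta2s2)
        A2 = t / eta2s
        # E(W^r|Y) = eta2* Phi(A2*) / (A2* Phi(A2*) + phi(A2*)) * E(V^{r+1})
        # with V ~ TN(A2*/eta2*, 1/eta2*^2); the prefactor equals
        # eta2* / (A2* + phi/Phi), stable through the scaled erfc.
        c = eta2s / (A2 + mills_inverse(A2))
        mom = truncnorm_moments(A2 / eta2s, 1.0 / eta2s, 3)
        return c * mom[1], c * mom[2]
    raise ValueError(
        f"posterior moments are closed-form only for the named families, "
        f"got {family!r}"
    )


def posterior_w_moments(Y, params: MMNParams):
    """Conditional moments (E(W|Y), E(W^2|Y)) of the mixing variable.

    Closed forms exist for the three named families: the posterior is a
    truncated normal for the skew-normal and exponential cases, and a
    length-biased truncated normal for the Weibull case.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape != (params.p, params.n):
        raise ValueError(
            f"Y has shape {Y.shape}, expected ({params.p}, {params.n})"
        )
    if not params.mixing.is_named:
        return posterior_w_moments_numeric(Y, params)
    _, t, eta2 = _base_logpdf_batch(Y[None], params)
    w_hat, t_hat = _posterior_moments_batch(t, eta2, params.mixing)
    return float(w_hat[0]), float(t_hat[0])


def posterior_w_moments_numeric(Y, params: MMNParams):
    """Posterior mixing moments by Bayes-rule quadrature (any mixing law)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mix = params.mixing
    log_f = mmn_logpdf_numeric(Y, params)
    lo, hi = mix.support

    def moment(order):
        val, _ = integrate.quad(
            lambda w: w**order
            * math.exp(
                matnorm_logpdf(
                    Y, params.M + w * params.Lambda, params.Sigma, params.Psi
                )
                - log_f
            )
            * float(mix.pdf(w)),
            lo,
            hi,
            limit=400,
        )
        return val

    return moment(1), moment(2)
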