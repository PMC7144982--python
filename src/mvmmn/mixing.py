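"""Scalar mixing laws for the mean-mixture-of-normal family.

The matrix law is built as ``Y = M + W*Lambda + X`` with ``X`` matrix normal
and ``W`` a scalar random variable, the *mixing* variable, independent of
``X``.  Three named laws admit closed-form matrix densities and posterior
moments:

``rsn``
    standard normal truncated to (0, inf) — gives the restricted
    matrix-variate skew-normal (RMVSN);
``exp1``
    unit-mean exponential — gives the exponentiated model (MVMMNE);
``weib21``
    Weibull with shape 2 and scale 1, density ``2 w exp(-w^2)`` — gives the
    mixed-Weibull model (MVMMNW).

Any other positive law can be supplied as a ``custom`` mixing law (a pdf and
a sampler); it is then handled purely numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate, special

__all__ = [
    "MixingLaw",
    "truncnorm_moments",
    "mills_inverse",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_NAMED_FAMILIES = ("rsn", "exp1", "weib21")


def mills_inverse(a):
    """Hazard ratio phi(a)/Phi(a) of the standard normal.

    Evaluated through the scaled complementary error function, so it is
    accurate to full relative precision arbitrarily far into the left tail
    (where both phi and Phi underflow individually).
    """
    a = np.asarray(a, dtype=float)
    return np.sqrt(2.0 / np.pi) / special.erfcx(-a / np.sqrt(2.0))


def truncnorm_moments(mu, sigma, r: int = 2):
    """Raw moments E(W), ..., E(W^r) of W ~ TN(mu, sigma^2; (0, inf)).

    Uses the first-moment closed form ``E(W) = mu + sigma*phi(a)/Phi(a)``
    with ``a = mu/sigma`` and the two-term recursion

        E(W^r) = mu E(W^{r-1}) + (r-1) sigma^2 E(W^{r-2}),   E(W^0) = 1.

    Parameters
    ----------
    mu, sigma : float or ndarray
        Location and scale of the parent normal; broadcast together.
        ``sigma`` must be positive.
    r : int
        Highest moment order, ``r >= 1``.

    Returns
    -------
    ndarray of shape ``(r,) + broadcast_shape`` holding E(W^1..W^r).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if r < 1:
        raise ValueError("moment order r must be >= 1")
    a = mu / sigma
    shape = np.broadcast_shapes(mu.shape, sigma.shape)
    scalar_input = shape == ()
    if scalar_input:
        shape = (1,)
    a_b = np.broadcast_to(a, shape)
    mu_b = np.broadcast_to(mu, shape)
    sigma_b = np.broadcast_to(sigma, shape)

    m_prev = np.ones(shape)
    m_curr = mu_b + sigma_b * mills_inverse(a_b)
    out = [m_curr]
    for order in range(2, r + 1):
        m_next = mu_b * m_curr + (order - 1) * sigma_b**2 * m_prev
        out.append(m_next)
        m_prev, m_curr = m_curr, m_next
    moments = np.stack(out, axis=0)

    # Deep left tail: the recursion cancels catastrophically for a << 0
    # (E(W^r) ~ r! (sigma/|a|)^r while each recursion term is O(sigma^r)).
    # There the law is an exponential with rate |a|/sigma times a gentle
    # Gaussian correction exp(-u^2/(2a^2)) in the scaled variable u, which
    # Gauss-Laguerre quadrature integrates to near machine precision.
    deep = a_b < -30.0
    if np.any(deep):
        ad = a_b[deep]
        rate = -ad / sigma_b[deep]  # lambda = |mu| / sigma^2, times sigma
        u, glw = _gauss_laguerre_nodes()
        damp = glw[:, None] * np.exp(-(u[:, None] ** 2) / (2.0 * ad[None, :] ** 2))
        s0 = damp.sum(axis=0)
        upow = np.ones_like(u)
        for order in range(1, r + 1):
            upow = upow * u
            s_r = (upow[:, None] * damp).sum(axis=0)
            moments[order - 1][deep] = s_r / s0 / rate**order
    if scalar_input:
        moments = moments[:, 0]
    return moments


_GL_CACHE = None


def _gauss_laguerre_nodes(k: int = 80):
    global _GL_CACHE
    if _GL_CACHE is None:
        _GL_CACHE = np.polynomial.laguerre.laggauss(k)
    return _GL_CACHE


@dataclass(frozen=True)
class MixingLaw:
    """Distribution of the scalar mixing variable W.

    Instances are built with the class-method constructors ``rsn()``,
    ``exp1()``, ``weib21()``, ``truncated_normal(mu, sigma)``,
    ``point_mass(c)`` or ``custom(...)``.  The three named families carry no
    free parameters, so ``nu`` is empty for them.
    """

    family: str
    nu: Tuple[float, ...] = ()
    support: Tuple[float, float] = (0.0, np.inf)
    _pdf: Optional[Callable] = field(default=None, repr=False)
    _rvs: Optional[Callable] = field(default=None, repr=False)
    _mean: Optional[float] = field(default=None, repr=False)
    _second_moment: Optional[float] = field(default=None, repr=False)
    _charf: Optional[Callable] = field(default=None, repr=False)

    # -- constructors -----------------------------------------------------

    @classmethod
    def rsn(cls) -> "MixingLaw":
        """Standard normal truncated to (0, inf)."""
        return cls(
            family="rsn",
            _pdf=lambda w: np.where(w > 0, 2.0 * _norm_pdf(w), 0.0),
            _rvs=lambda size, rng: np.abs(rng.standard_normal(size)),
            _mean=math.sqrt(2.0 / math.pi),
            _second_moment=1.0,
            _charf=lambda t: np.exp(-0.5 * np.asarray(t) ** 2)
            * (1.0 + 1j * special.erfi(np.asarray(t) / math.sqrt(2.0))),
        )

    @classmethod
    def exp1(cls) -> "MixingLaw":
        """Exponential with mean 1."""
        return cls(
            family="exp1",
            _pdf=lambda w: np.where(w > 0, np.exp(-np.clip(w, 0, None)), 0.0),
            _rvs=lambda size, rng: rng.exponential(size=size),
            _mean=1.0,
            _second_moment=2.0,
            _charf=lambda t: 1.0 / (1.0 - 1j * np.asarray(t)),
        )

    @classmethod
    def weib21(cls) -> "MixingLaw":
        """Weibull, shape 2 scale 1: h(w) = 2 w exp(-w^2) on (0, inf)."""
        return cls(
            family="weib21",
            _pdf=lambda w: np.where(w > 0, 2.0 * w * np.exp(-np.square(w)), 0.0),
            _rvs=lambda size, rng: rng.rayleigh(scale=1.0 / math.sqrt(2.0), size=size),
            _mean=math.sqrt(math.pi) / 2.0,  # Gamma(3/2)
            _second_moment=1.0,  # Gamma(2)
            _charf=_weib21_charf,
        )

    @classmethod
    def truncated_normal(cls, mu: float, sigma: float) -> "MixingLaw":
        """TN(mu, sigma^2; (0, inf)) — e.g. a conditional mixing law."""
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        mom = truncnorm_moments(mu, sigma, 2)
        a = mu / sigma
        log_norm = special.log_ndtr(a)

        def pdf(w):
            w = np.asarray(w, dtype=float)
            z = (w - mu) / sigma
            val = np.exp(-0.5 * z**2 - log_norm) / (sigma * _SQRT_2PI)
            return np.where(w > 0, val, 0.0)

        def rvs(size, rng):
            # inverse-cdf draw on the (0, inf) slice of the parent normal
            lo = special.ndtr(-mu / sigma)
            u = rng.uniform(lo, 1.0, size=size)
            return mu + sigma * special.ndtri(u)

        return cls(
            family="truncnorm",
            nu=(float(mu), float(sigma)),
            _pdf=pdf,
            _rvs=rvs,
            _mean=float(mom[0]),
            _second_moment=float(mom[1]),
        )

    @classmethod
    def point_mass(cls, c: float) -> "MixingLaw":
        """Degenerate mixing W == c (used to express pure matrix normals)."""
        return cls(
            family="point",
            nu=(float(c),),
            support=(c, c),
            _rvs=lambda size, rng: np.full(size, float(c)),
            _mean=float(c),
            _second_moment=float(c) ** 2,
            _charf=lambda t: np.exp(1j * c * np.asarray(t)),
        )

    @classmethod
    def custom(
        cls,
        pdf: Callable,
        sampler: Optional[Callable] = None,
        support: Tuple[float, float] = (0.0, np.inf),
        nu: Tuple[float, ...] = (),
    ) -> "MixingLaw":
        """A user-supplied law; handled through quadrature only.

        ``sampler(size, rng)`` is optional and only needed for ``rvs``.
        """
        return cls(family="custom", nu=nu, support=support, _pdf=pdf, _rvs=sampler)

    # -- behaviour --------------------------------------------------------

    @property
    def is_named(self) -> bool:
        return self.family in _NAMED_FAMILIES

    def pdf(self, w):
        if self._pdf is None:
            raise NotImplementedError(f"{self.family} mixing has no density")
        return self._pdf(np.asarray(w, dtype=float))

    def rvs(self, size, rng: np.random.Generator):
        if self._rvs is None:
            raise NotImplementedError(f"{self.family} mixing has no sampler")
        return self._rvs(size, rng)

    def mean(self) -> float:
        if self._mean is not None:
            return self._mean
        val = self._numeric_moment(1)
        if not np.isfinite(val):
            raise ValueError(f"mixing law {self.family!r} has no finite mean")
        return val

    def second_moment(self) -> float:
        if self._second_moment is not None:
            return self._second_moment
        return self._numeric_moment(2)

    def char_function(self, t):
        if self._charf is not None:
            return self._charf(t)
        lo, hi = self.support
        t = float(t)
        re, _ = integrate.quad(lambda w: np.cos(t * w) * self.pdf(w), lo, hi, limit=200)
        im, _ = integrate.quad(lambda w: np.sin(t * w) * self.pdf(w), lo, hi, limit=200)
        return re + 1j * im

    def _numeric_moment(self, order: int) -> float:
        lo, hi = self.support
        val, _ = integrate.quad(
            lambda w: w**order * self.pdf(w), lo, hi, limit=200
        )
        return val

    def check_normalized(self, tol: float = 1e-6) -> float:
        """Numeric integral of the pdf over the support; raises if not ~1."""
        if self.family == "point":
            return 1.0
        lo, hi = self.support
        total, _ = integrate.quad(lambda w: self.pdf(w), lo, hi, limit=200)
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"mixing pdf integrates to {total:.8f}, not 1 (family={self.family})"
            )
        return total


def _norm_pdf(w):
    return np.exp(-0.5 * np.square(w)) / _SQRT_2PI


def _weib21_charf(t):
    t = np.asarray(t, dtype=float)
    # E exp(itW) for h(w) = 2w exp(-w^2):
    # 1 + i sqrt(pi) (t/2) exp(-t^2/4) (1 + i erfi(t/2))
    return 1.0 + 1j * math.sqrt(math.pi) * (t / 2.0) * np.exp(-(t**2) / 4.0) * (
        1.0 + 1j * special.erfi(t / 2.0)
    )
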