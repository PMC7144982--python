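"""Maximum-likelihood fitting of the named MVMMN models by ECM.

The complete-data likelihood treats the mixing draws ``w_i`` as latent.  The
E-step needs only the per-observation conditional moments
``w_hat_i = E(W | Y_i)`` and ``t_hat_i = E(W^2 | Y_i)`` (closed forms for the
three named families); the CM-steps then update (M, Lambda) and
(Sigma, Psi) in turn, each in closed form:

    Lambda_new = [mean(w_hat_i Y_i) - w_bar mean(Y_i)] / (t_bar - w_bar^2)
    M_new      = mean(Y_i) - Lambda_new * w_bar
    Sigma_new  = (1/Nn) sum_i { E_i Psi^-1 E_i' + t_i L Psi^-1 L'
                                - w_i (L Psi^-1 E_i' + E_i Psi^-1 L') }
    Psi_new    = same with rows/columns swapped and the fresh Sigma_new,

with ``E_i = Y_i - M_new`` and ``L = Lambda_new``.  (M, Lambda) are updated
jointly — the pair above solves the joint stationarity system of the
Q-function, so the step is an exact conditional maximization and the
observed log-likelihood ascends monotonically.  Convergence is judged by
Aitken acceleration of the log-likelihood sequence by default.

Two identifiability wrinkles are handled inside ``fit``:

* the Kronecker scale pair is only identified up to ``(c Sigma, Psi / c)``
  and the whole ECM trajectory is equivariant under that rescaling, so the
  split is pinned by the convention ``tr(Psi) = n`` (average unit column
  variance), applied every iteration; the log-likelihood is invariant;
* the iteration self-reinforces the sign of the starting skewness, so the
  default start burns in from both ``Lambda = +1`` and ``Lambda = -1`` and
  continues the branch with the higher log-likelihood.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import linalg

from .dataset import MatrixDataset
from .density import _base_logpdf_batch, _chol, _mmn_logpdf_batch, _posterior_moments_batch
from .mixing import MixingLaw
from .params import MMNParams

__all__ = [
    "ECMConfig",
    "EStepQuantities",
    "ConvergenceMonitor",
    "FitResult",
    "free_parameter_count",
    "information_criteria",
    "initialize",
    "e_step",
    "cm_update_location",
    "cm_update_scale",
    "loglikelihood",
    "fit",
]

_FAMILY_LABELS = {"rsn": "RMVSN", "exp1": "MVMMNE", "weib21": "MVMMNW"}
_MIXING_FACTORIES = {
    "rsn": MixingLaw.rsn,
    "exp1": MixingLaw.exp1,
    "weib21": MixingLaw.weib21,
}


@dataclass
class ECMConfig:
    """Knobs of the ECM iteration.

    ``stopping`` is one of ``"aitken"`` (default: stop when the Aitken
    asymptotic log-likelihood estimate is within ``tol`` of the current
    value), ``"loglik-diff"`` or ``"param-diff"``.
    """

    tol: float = 1e-5
    max_iter: int = 2000
    stopping: str = "aitken"
    init: Optional[MMNParams] = None
    normalize_scale: bool = True
    dual_start_burnin: int = 30

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.stopping not in ("aitken", "loglik-diff", "param-diff"):
            raise ValueError(f"unknown stopping rule {self.stopping!r}")

    @classmethod
    def from_yaml(cls, path) -> "ECMConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class EStepQuantities:
    """Per-observation conditional mixing moments and their averages."""

    w_hat: np.ndarray
    t_hat: np.ndarray

    @property
    def w_bar(self) -> float:
        return float(self.w_hat.mean())

    @property
    def t_bar(self) -> float:
        return float(self.t_hat.mean())


@dataclass
class ConvergenceMonitor:
    """Log-likelihood trajectory and Aitken diagnostics."""

    loglik: List[float] = field(default_factory=list)
    aitken: List[float] = field(default_factory=list)
    loglik_inf: List[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def free_parameter_count(p: int, n: int) -> int:
    """m = 2pn + p(p+1)/2 + n(n+1)/2 (location, skewness, two scales)."""
    return 2 * p * n + p * (p + 1) // 2 + n * (n + 1) // 2


def information_criteria(loglik_max: float, m: int, N: int):
    """(AIC, BIC) = (2m - 2 l_max, m log N - 2 l_max)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return 2.0 * m - 2.0 * loglik_max, m * math.log(N) - 2.0 * loglik_max


@dataclass
class FitResult:
    """Estimates, trajectory and model-selection criteria of one ECM fit."""

    params: MMNParams
    estep: EStepQuantities
    monitor: ConvergenceMonitor
    loglik: float
    m: int
    aic: float
    bic: float
    N: int

    @property
    def family(self) -> str:
        return self.params.mixing.family

    @property
    def converged(self) -> bool:
        return self.monitor.converged

    @property
    def n_iter(self) -> int:
        return self.monitor.n_iter

    def summary(self) -> str:
        label = _FAMILY_LABELS.get(self.family, self.family)
        lines = [
            "Matrix mean-mixture of normal — ECM maximum likelihood",
            "=" * 58,
            f"model:          {label} ({self.family} mixing)",
            f"observations:   N = {self.N}, matrix shape {self.params.p} x {self.params.n}",
            f"log-likelihood: {self.loglik:.4f}",
            f"free params:    m = {self.m}",
            f"AIC:            {self.aic:.4f}",
            f"BIC:            {self.bic:.4f}",
            f"iterations:     {self.n_iter} (converged: {self.converged})",
            "-" * 58,
        ]
        for name, mat in (
            ("M", self.params.M),
            ("Lambda", self.params.Lambda),
            ("Sigma", self.params.Sigma),
            ("Psi", self.params.Psi),
        ):
            lines.append(f"{name} =")
            lines.append(np.array2string(mat, precision=4, suppress_small=True))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "N": self.N,
            "p": self.params.p,
            "n": self.params.n,
            "M": self.params.M.tolist(),
            "Lambda": self.params.Lambda.tolist(),
            "Sigma": self.params.Sigma.tolist(),
            "Psi": self.params.Psi.tolist(),
            "loglik": self.loglik,
            "m": self.m,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik_trajectory": list(self.monitor.loglik),
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def trajectory_to_csv(self, path) -> None:
        arr = np.column_stack(
            [np.arange(len(self.monitor.loglik)), self.monitor.loglik]
        )
        np.savetxt(path, arr, delimiter=",", header="iteration,loglik")


# ---------------------------------------------------------------------------
# algorithm pieces


def initialize(data: MatrixDataset) -> MMNParams:
    """Moment-free starting point: sample-mean location, all-ones skewness,
    diagonal scales from per-row / per-column sums of squared deviations.

    The scale seeds are raw sums (not averages): for row j,
    ``c1_j = sum_i sum_l (y_ijl - ybar_j)^2`` with ``ybar_j`` the grand mean
    of row j over observations and columns, and symmetrically for columns.
    """
    if data.N < 2:
        raise ValueError("initialization needs N >= 2 observations")
    Ys = data.observations
    M0 = Ys.mean(axis=0)
    row_means = Ys.mean(axis=(0, 2))  # ybar_j over i and l
    col_means = Ys.mean(axis=(0, 1))  # ybar_l over i and j
    c1 = np.sum((Ys - row_means[None, :, None]) ** 2, axis=(0, 2))
    c2 = np.sum((Ys - col_means[None, None, :]) ** 2, axis=(0, 1))
    # relative floor: catches exactly-constant slices up to rounding noise
    floor = 1e-12 * max(float(np.max(c1)), float(np.max(c2)), 1.0)
    if np.any(c1 <= floor) or np.any(c2 <= floor):
        bad_rows = np.nonzero(c1 <= floor)[0].tolist()
        bad_cols = np.nonzero(c2 <= floor)[0].tolist()
        raise ValueError(
            "degenerate scale initialization: zero spread in "
            f"rows {bad_rows} / columns {bad_cols}"
        )
    return MMNParams(
        M0, np.ones((data.p, data.n)), np.diag(c1), np.diag(c2), MixingLaw.rsn()
    )


def loglikelihood(data: MatrixDataset, params: MMNParams) -> float:
    """Observed-data log-likelihood sum_i log f(Y_i; params)."""
    return float(np.sum(_mmn_logpdf_batch(data.observations, params)))


def e_step(data: MatrixDataset, params: MMNParams) -> EStepQuantities:
    """Conditional mixing moments for every observation."""
    _, t, eta2 = _base_logpdf_batch(data.observations, params)
    w_hat, t_hat = _posterior_moments_batch(t, eta2, params.mixing)
    return EStepQuantities(w_hat=np.asarray(w_hat), t_hat=np.asarray(t_hat))


def cm_update_location(
    data: MatrixDataset, estep: EStepQuantities, Lambda_previous=None
):
    """First CM-step: new (M, Lambda).

    The skewness update is location-free.  By default the location update
    uses the *new* skewness — the pair then solves the joint stationarity
    system of the Q-function in (M, Lambda), so the step is an exact joint
    maximization and the EM ascent property holds.  Passing
    ``Lambda_previous`` instead plugs the previous skewness iterate into
    the location update (same fixed points, no ascent guarantee).
    """
    Ys = data.observations
    w_bar, t_bar = estep.w_bar, estep.t_bar
    denom = t_bar - w_bar**2
    if denom <= 1e-12:
        raise FloatingPointError(
            "degenerate mixing posterior: Var-type denominator "
            f"t_bar - w_bar^2 = {denom:.3e} <= 1e-12"
        )
    Y_bar = Ys.mean(axis=0)
    wY_bar = np.einsum("i,ipn->pn", estep.w_hat, Ys) / data.N
    Lambda_new = (wY_bar - w_bar * Y_bar) / denom
    Lambda_loc = (
        Lambda_new
        if Lambda_previous is None
        else np.asarray(Lambda_previous, dtype=float)
    )
    M_new = Y_bar - Lambda_loc * w_bar
    return M_new, Lambda_new


def _spd_repair(mat: np.ndarray, name: str) -> np.ndarray:
    """Symmetrize and, if needed, jitter the diagonal until Cholesky passes."""
    mat = 0.5 * (mat + mat.T)
    jitter = 0.0
    for _ in range(6):
        try:
            np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-8 if jitter == 0.0 else jitter * 100.0
    else:
        raise np.linalg.LinAlgError(f"{name} update is irreparably non-SPD")
    if jitter > 0.0:
        warnings.warn(
            f"{name} update required {jitter:.1e} diagonal jitter",
            RuntimeWarning,
            stacklevel=3,
        )
        mat = mat + jitter * np.eye(mat.shape[0])
    return mat


def cm_update_scale(
    data: MatrixDataset,
    estep: EStepQuantities,
    M_new,
    Lambda_new,
    Psi_current,
):
    """Second CM-step: Sigma then Psi (Psi uses the fresh Sigma)."""
    Ys = data.observations
    N, p, n = Ys.shape
    E = Ys - np.asarray(M_new, dtype=float)[None]
    Lam = np.asarray(Lambda_new, dtype=float)
    w, t = estep.w_hat, estep.t_hat

    L_p = _chol(Psi_current, "Psi")
    K_psi = linalg.cho_solve((L_p, True), np.eye(n))
    Ew = np.einsum("i,ipn->pn", w, E)
    quad = np.einsum("ipn,nm,iqm->pq", E, K_psi, E)
    cross = Lam @ K_psi @ Ew.T
    Sigma_new = (
        quad + float(t.sum()) * Lam @ K_psi @ Lam.T - cross - cross.T
    ) / (N * n)
    Sigma_new = _spd_repair(Sigma_new, "Sigma")

    L_s = _chol(Sigma_new, "Sigma")
    K_sig = linalg.cho_solve((L_s, True), np.eye(p))
    quad_c = np.einsum("ipn,pq,iqm->nm", E, K_sig, E)
    cross_c = Lam.T @ K_sig @ Ew
    Psi_new = (
        quad_c + float(t.sum()) * Lam.T @ K_sig @ Lam - cross_c - cross_c.T
    ) / (N * p)
    Psi_new = _spd_repair(Psi_new, "Psi")
    return Sigma_new, Psi_new


def _mixing_for(family: str) -> MixingLaw:
    try:
        return _MIXING_FACTORIES[family]()
    except KeyError:
        raise ValueError(
            f"ECM fitting supports the named families {tuple(_MIXING_FACTORIES)}, "
            f"got {family!r}"
        ) from None


def _normalize_split(Sigma, Psi, n: int):
    """Pin the non-identified Kronecker split by tr(Psi) = n."""
    c = float(np.trace(Psi)) / n
    return Sigma * c, Psi / c


def _ecm_cycle(data, params, mixing, config):
    """One E-step + both CM-steps; returns (new_params, estep)."""
    estep = e_step(data, params)
    M_new, Lam_new = cm_update_location(data, estep)
    Sigma_new, Psi_new = cm_update_scale(data, estep, M_new, Lam_new, params.Psi)
    if config.normalize_scale:
        Sigma_new, Psi_new = _normalize_split(Sigma_new, Psi_new, data.n)
    return MMNParams(M_new, Lam_new, Sigma_new, Psi_new, mixing), estep


def _starting_points(data, family, config, mixing):
    """Candidate starts: a supplied one, or the seeded rule with +/-1 skew.

    The diagonal profiles of the starting scales come from
    :func:`initialize`; their overall scale is then moment-matched so that
    tr(Sigma0) tr(Psi0) equals the total entrywise sample variance (the
    matrix-normal identity sum_jl Var(Y_jl) = tr(Sigma) tr(Psi)).  Without
    this the raw seed product is ~N^2 times too large and the skewness
    statistic underflows into the absorbing Lambda = 0 fixed point.

    The iteration also self-reinforces the sign of the starting skewness
    matrix, so both orientations of the all-ones start are burned in and
    the branch with the higher log-likelihood is kept.
    """
    if config.init is not None:
        return [config.init.replace(mixing=mixing)]
    base = initialize(data).replace(mixing=mixing)
    v_tot = float(np.sum(np.var(data.observations, axis=0)))
    s1 = float(np.trace(base.Sigma))
    s2 = float(np.trace(base.Psi))
    gamma = math.sqrt(v_tot / (s1 * s2))
    Sigma0, Psi0 = gamma * base.Sigma, gamma * base.Psi
    if config.normalize_scale:
        Sigma0, Psi0 = _normalize_split(Sigma0, Psi0, data.n)
    base = base.replace(Sigma=Sigma0, Psi=Psi0)
    return [base, base.replace(Lambda=-base.Lambda)]


def fit(
    data: MatrixDataset,
    family: str = "rsn",
    config: Optional[ECMConfig] = None,
) -> FitResult:
    """Run the ECM iteration to convergence for one named mixing family.

    Deterministic given data and configuration — the algorithm contains no
    randomness.
    """
    if config is None:
        config = ECMConfig()
    if data.N < 2:
        raise ValueError("fitting needs N >= 2 observations")
    mixing = _mixing_for(family)

    starts = _starting_points(data, family, config, mixing)
    branches = []
    for params0 in starts:
        ll = loglikelihood(data, params0)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood at the starting point")
        traj = [ll]
        params = params0
        burnin = min(config.dual_start_burnin, config.max_iter) if len(starts) > 1 else 0
        for _ in range(burnin):
            params, _ = _ecm_cycle(data, params, mixing, config)
            traj.append(loglikelihood(data, params))
        branches.append((params, traj))
    params, loglik_traj = max(branches, key=lambda b: b[1][-1])

    monitor = ConvergenceMonitor()
    monitor.loglik = list(loglik_traj)
    monitor.n_iter = len(loglik_traj) - 1

    for k in range(monitor.n_iter + 1, config.max_iter + 1):
        new_params, estep = _ecm_cycle(data, params, mixing, config)
        ll_new = loglikelihood(data, new_params)
        if not np.isfinite(ll_new):
            raise FloatingPointError(
                f"non-finite log-likelihood at iteration {k} ({family})"
            )
        monitor.loglik.append(ll_new)
        monitor.n_iter = k

        if config.stopping == "param-diff":
            delta = max(
                float(np.max(np.abs(new_params.M - params.M))),
                float(np.max(np.abs(new_params.Lambda - params.Lambda))),
                float(np.max(np.abs(new_params.Sigma - params.Sigma))),
                float(np.max(np.abs(new_params.Psi - params.Psi))),
            )
            stop = delta < config.tol
        elif config.stopping == "loglik-diff":
            stop = abs(ll_new - monitor.loglik[-2]) < config.tol
        else:  # aitken
            stop = False
            if len(monitor.loglik) >= 3:
                l2, l1, l0 = monitor.loglik[-1], monitor.loglik[-2], monitor.loglik[-3]
                denom = l1 - l0
                if abs(denom) > 0:
                    a = (l2 - l1) / denom
                    monitor.aitken.append(a)
                    if 0.0 < a < 1.0:
                        l_inf = l2 + (l2 - l1) / (1.0 - a)
                        monitor.loglik_inf.append(l_inf)
                        stop = 0.0 <= (l_inf - l1) < config.tol
                    else:
                        # acceleration undefined; fall back to plain difference
                        stop = abs(l2 - l1) < config.tol
                else:
                    stop = True

        params = new_params
        if stop:
            monitor.converged = True
            break

    estep = e_step(data, params)
    ll_max = monitor.loglik[-1]
    m = free_parameter_count(data.p, data.n)
    aic, bic = information_criteria(ll_max, m, data.N)
    return FitResult(
        params=params,
        estep=estep,
        monitor=monitor,
        loglik=ll_max,
        m=m,
        aic=aic,
        bic=bic,
        N=data.N,
    )
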