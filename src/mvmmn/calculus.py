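"""Moments, characteristic function and closure laws of the MVMMN family.

The family is closed under transposition, full-rank affine maps ``B Y D``,
block marginals, and row/column conditioning; the conditional law keeps the
MVMMN form with the mixing variable replaced by its posterior given the
observed block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .density import _chol, matnorm_logpdf, mmn_sample, skew_summaries
from .mixing import MixingLaw
from .params import MMNParams

__all__ = [
    "PartitionSpec",
    "QuadraticFormSpec",
    "mmn_mean",
    "mmn_char_function",
    "mmn_elementwise_second_moment",
    "mmn_trace_second_moment",
    "transpose_params",
    "affine_transform",
    "marginal_params",
    "conditional_params",
    "quadratic_form_spec",
    "quadratic_form_mc_check",
]


@dataclass(frozen=True)
class PartitionSpec:
    """Interior split points for block partitions.

    ``row_split=q`` separates the first q rows; ``col_split=m`` the first m
    columns.  At least one must be given; each must be strictly interior
    relative to the parameter dimensions it is applied to.
    """

    row_split: Optional[int] = None
    col_split: Optional[int] = None

    def validate(self, p: int, n: int, require_single_axis: bool = False):
        if self.row_split is None and self.col_split is None:
            raise ValueError("partition needs a row_split and/or col_split")
        if self.row_split is not None and not (1 <= self.row_split < p):
            raise ValueError(f"row_split must lie in [1, {p - 1}]")
        if self.col_split is not None and not (1 <= self.col_split < n):
            raise ValueError(f"col_split must lie in [1, {n - 1}]")
        if require_single_axis and (
            self.row_split is not None and self.col_split is not None
        ):
            raise ValueError("conditioning is row-wise or column-wise, not both")


def mmn_mean(params: MMNParams) -> np.ndarray:
    """E(Y) = M + E(W) Lambda."""
    return params.M + params.mixing.mean() * params.Lambda


def mmn_char_function(T, params: MMNParams) -> complex:
    """Characteristic function etr{i T'M - T'Sigma T Psi / 2} phi_W(tr(T'Lambda))."""
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape != (params.p, params.n):
        raise ValueError(f"T has shape {T.shape}, expected ({params.p}, {params.n})")
    lin = np.trace(T.T @ params.M)
    quad = np.trace(T.T @ params.Sigma @ T @ params.Psi)
    skew = np.trace(T.T @ params.Lambda)
    return np.exp(1j * lin - 0.5 * quad) * complex(params.mixing.char_function(skew))


def mmn_elementwise_second_moment(params: MMNParams, i1, j1, i2, j2) -> float:
    """E(Y_{i1 j1} Y_{i2 j2}).

    The normal contribution is the matrix-normal second moment
    sigma_{i1 i2} psi_{j1 j2}; the mixing variable adds location and
    skewness cross terms through E(W) and E(W^2).
    """
    m1, m2 = params.M[i1, j1], params.M[i2, j2]
    l1, l2 = params.Lambda[i1, j1], params.Lambda[i2, j2]
    ew = params.mixing.mean()
    ew2 = params.mixing.second_moment()
    return (
        params.Sigma[i1, i2] * params.Psi[j1, j2]
        + m1 * m2
        + ew * (m1 * l2 + l1 * m2)
        + ew2 * l1 * l2
    )


def mmn_trace_second_moment(params: MMNParams) -> float:
    """E(tr(Y Y^T)) for a zero-location law: E(W^2) sum(Lambda^2) + tr(Sigma) tr(Psi)."""
    if not np.allclose(params.M, 0.0):
        raise ValueError("trace second-moment formula is valid only for M = 0")
    ew2 = params.mixing.second_moment()
    return float(
        ew2 * np.sum(params.Lambda**2)
        + np.trace(params.Sigma) * np.trace(params.Psi)
    )


def transpose_params(params: MMNParams) -> MMNParams:
    """Parameters of Y^T: (M^T, Lambda^T, Psi, Sigma, same mixing)."""
    return MMNParams(
        params.M.T, params.Lambda.T, params.Psi, params.Sigma, params.mixing
    )


def affine_transform(params: MMNParams, B, D) -> MMNParams:
    """Parameters of B Y D for full-rank B (q x p) and D (n x m).

    The transformed law is MVMMN with location BMD, skewness B Lambda D,
    row scale B Sigma B', column scale D' Psi D, and the unchanged mixing
    variable.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if B.shape[1] != params.p or D.shape[0] != params.n:
        raise ValueError(
            f"B must have {params.p} columns and D {params.n} rows, got "
            f"{B.shape} and {D.shape}"
        )
    Sigma_new = B @ params.Sigma @ B.T
    Psi_new = D.T @ params.Psi @ D
    # symmetrize against roundoff; MMNParams re-checks positive definiteness
    Sigma_new = 0.5 * (Sigma_new + Sigma_new.T)
    Psi_new = 0.5 * (Psi_new + Psi_new.T)
    return MMNParams(
        B @ params.M @ D, B @ params.Lambda @ D, Sigma_new, Psi_new, params.mixing
    )


def _row_selector(q: int, p: int) -> np.ndarray:
    return np.eye(p)[:q]


def marginal_params(params: MMNParams, part: PartitionSpec, block: str = "11") -> MMNParams:
    """Parameters of a block marginal, via selector-matrix affine transforms.

    ``block`` picks which corner of the partition to keep: one of
    ``"11", "12", "21", "22"`` (missing splits keep the full axis).
    """
    p, n = params.p, params.n
    part.validate(p, n)
    q = part.row_split if part.row_split is not None else p
    m = part.col_split if part.col_split is not None else n
    if block not in ("11", "12", "21", "22"):
        raise ValueError(f"unknown block {block!r}")
    rows_first = block[0] == "1"
    cols_first = block[1] == "1"
    B = _row_selector(q, p) if rows_first else np.eye(p)[q:]
    D = (_row_selector(m, n) if cols_first else np.eye(n)[m:]).T
    return affine_transform(params, B, D)


def conditional_params(
    params: MMNParams, part: PartitionSpec, observed_block
) -> MMNParams:
    """Law of the remaining block given an observed leading block.

    For a row partition at ``q``, returns the parameters of
    ``Y2 | Y1 = observed_block`` where ``Y1`` holds the first ``q`` rows:
    Schur-complement location and scale, transformed skewness, and the
    conditional mixing law W | Y1.  The conditional mixing is a truncated
    normal in closed form for the ``rsn`` and ``exp1`` families; for any
    other family it is the numeric posterior density.
    """
    part.validate(params.p, params.n, require_single_axis=True)
    if part.row_split is not None:
        work = params
        q = part.row_split
        transpose_back = False
    else:
        # column conditioning is row conditioning of the transposed law
        work = transpose_params(params)
        q = part.col_split
        transpose_back = True

    Y1 = np.atleast_2d(np.asarray(observed_block, dtype=float))
    if transpose_back:
        Y1 = Y1.T  # observed columns become rows of the transposed law
    if Y1.shape != (q, work.n):
        raise ValueError(
            f"observed block has shape {Y1.shape}, expected ({q}, {work.n})"
        )

    S11 = work.Sigma[:q, :q]
    S21 = work.Sigma[q:, :q]
    S22 = work.Sigma[q:, q:]
    L11 = _chol(S11, "Sigma11")
    reg = linalg.cho_solve((L11, True), S21.T).T  # Sigma21 Sigma11^-1
    M_cond = work.M[q:] + reg @ (Y1 - work.M[:q])
    Lam_cond = work.Lambda[q:] - reg @ work.Lambda[:q]
    S_cond = S22 - reg @ S21.T
    S_cond = 0.5 * (S_cond + S_cond.T)

    marg = MMNParams(work.M[:q], work.Lambda[:q], S11, work.Psi, work.mixing)
    mixing_cond = _posterior_mixing_law(Y1, marg)

    out = MMNParams(M_cond, Lam_cond, S_cond, work.Psi, mixing_cond)
    return transpose_params(out) if transpose_back else out


def _posterior_mixing_law(Y1, marg: MMNParams) -> MixingLaw:
    """Law of W given an observed marginal block."""
    family = marg.mixing.family
    s = skew_summaries(Y1, marg)
    if family == "rsn":
        eta = math.sqrt(s.eta2)
        return MixingLaw.truncated_normal(s.A / eta, 1.0 / eta)
    if family == "exp1":
        if not s.a1s_defined:
            return marg.mixing  # Lambda block is zero: posterior = prior
        eta1s = math.sqrt(s.eta1s2)
        return MixingLaw.truncated_normal(s.A1s / eta1s, 1.0 / eta1s)
    # numeric posterior: h(w | Y1) ∝ phi(Y1; M1 + w Lam1, S11, Psi) h(w)
    from .density import mmn_logpdf_numeric

    log_f = mmn_logpdf_numeric(Y1, marg)
    prior = marg.mixing

    def pdf(w):
        w = np.atleast_1d(np.asarray(w, dtype=float))
        out = np.empty_like(w)
        for k, wk in enumerate(w):
            out[k] = float(prior.pdf(wk)) * math.exp(
                matnorm_logpdf(Y1, marg.M + wk * marg.Lambda, marg.Sigma, marg.Psi)
                - log_f
            )
        return out if out.size > 1 else float(out[0])

    return MixingLaw.custom(pdf, support=prior.support)


# ---------------------------------------------------------------------------
# quadratic forms


@dataclass(frozen=True)
class QuadraticFormSpec:
    """Eigen-structure of the quadratic form Y A Y^T given W = w.

    ``deltas`` are the nonzero eigenvalues of ``Psi^{1/2} A Psi^{1/2}``
    (equivalently of ``A Psi``), ``vectors`` the matching orthonormal
    eigenvectors, and ``noncentrality`` the vectors ``m_j`` so that
    ``Y A Y^T | W=w`` equals ``sum_j delta_j x_j x_j^T`` in law with
    ``x_j ~ N_p(m_j, Sigma)`` independent.
    """

    deltas: np.ndarray
    vectors: np.ndarray  # (n, r) columns a_j
    noncentrality: np.ndarray  # (p, r) columns m_j


def _sym_sqrt(mat: np.ndarray):
    vals, vecs = np.linalg.eigh(mat)
    if np.any(vals <= 0):
        raise np.linalg.LinAlgError("matrix square root needs positive eigenvalues")
    root = vecs @ np.diag(np.sqrt(vals)) @ vecs.T
    inv_root = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    return root, inv_root


def quadratic_form_spec(params: MMNParams, A, w: float) -> QuadraticFormSpec:
    """Decompose Y A Y^T | W = w into independent rank-one Wishart terms."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape != (params.n, params.n):
        raise ValueError(f"A must be {params.n} x {params.n}")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("A must be symmetric")
    root, inv_root = _sym_sqrt(params.Psi)
    S = root @ A @ root
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    keep = np.abs(vals) > 1e-12 * max(1.0, float(np.abs(vals).max(initial=0.0)))
    deltas = vals[keep]
    a = vecs[:, keep]
    # conditionally on W = w the location of Y is M + w Lambda, and of the
    # whitened Y Psi^{-1/2} it is (M + w Lambda) Psi^{-1/2}
    M_w = (params.M + w * params.Lambda) @ inv_root
    return QuadraticFormSpec(deltas=deltas, vectors=a, noncentrality=M_w @ a)


def quadratic_form_mc_check(
    params: MMNParams, A, w: float, n_draws: int = 100_000, seed=None
) -> dict:
    """Monte-Carlo check that Y A Y^T | W=w matches its eigen-decomposition.

    Samples the quadratic form directly and through the sum of scaled
    rank-one Wishart draws, then compares elementwise means within a
    standard-error band.  This is a verification utility, not an inference
    tool.  Returns a JSON-serializable report.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    spec = quadratic_form_spec(params, A, w)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, n = params.p, params.n

    cond = MMNParams(
        params.M + w * params.Lambda,
        np.zeros((p, n)),
        params.Sigma,
        params.Psi,
        MixingLaw.point_mass(0.0),
    )
    Ys = mmn_sample(cond, n_draws, seed=rng).observations
    Q = np.einsum("ipn,nm,iqm->ipq", Ys, A, Ys)

    L_s = _chol(params.Sigma, "Sigma")
    r = spec.deltas.size
    B = np.zeros((n_draws, p, p))
    for j in range(r):
        x = spec.noncentrality[:, j][None, :] + rng.standard_normal(
            (n_draws, p)
        ) @ L_s.T
        B += spec.deltas[j] * np.einsum("ip,iq->ipq", x, x)

    mean_q, mean_b = Q.mean(axis=0), B.mean(axis=0)
    se = np.sqrt(Q.var(axis=0) / n_draws + B.var(axis=0) / n_draws)
    se = np.where(se > 0, se, 1e-12)
    z = (mean_q - mean_b) / se
    return {
        "deltas": spec.deltas.tolist(),
        "mean_direct": mean_q.tolist(),
        "mean_decomposed": mean_b.tolist(),
        "max_abs_z": float(np.abs(z).max()),
        "n_draws": int(n_draws),
        "agrees_4se": bool(np.abs(z).max() < 4.0),
    }
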