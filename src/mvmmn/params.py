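"""Parameter set of the matrix-variate mean-mixture-of-normal model."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mixing import MixingLaw

__all__ = ["MMNParams"]


def _as_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"{name} is not positive definite") from err
    return mat


@dataclass(frozen=True)
class MMNParams:
    """Full parameter set (M, Lambda, Sigma, Psi, mixing law).

    ``M`` is the p x n location, ``Lambda`` the p x n skewness matrix,
    ``Sigma`` the p x p row scale and ``Psi`` the n x n column scale (both
    symmetric positive definite).  ``mixing`` is the law of the scalar
    mixing variable W.
    """

    M: np.ndarray
    Lambda: np.ndarray
    Sigma: np.ndarray
    Psi: np.ndarray
    mixing: MixingLaw

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        Lam = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        if M.shape != Lam.shape:
            raise ValueError(
                f"M has shape {M.shape} but Lambda has shape {Lam.shape}"
            )
        Sigma = _as_spd(self.Sigma, "Sigma")
        Psi = _as_spd(self.Psi, "Psi")
        p, n = M.shape
        if Sigma.shape != (p, p):
            raise ValueError(f"Sigma has shape {Sigma.shape}, expected ({p}, {p})")
        if Psi.shape != (n, n):
            raise ValueError(f"Psi has shape {Psi.shape}, expected ({n}, {n})")
        if not (np.all(np.isfinite(M)) and np.all(np.isfinite(Lam))):
            raise ValueError("M and Lambda must be finite")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "Lambda", Lam)
        object.__setattr__(self, "Sigma", Sigma)
        object.__setattr__(self, "Psi", Psi)

    @property
    def p(self) -> int:
        return self.M.shape[0]

    @property
    def n(self) -> int:
        return self.M.shape[1]

    @property
    def family(self) -> str:
        return self.mixing.family

    def replace(self, **kwargs) -> "MMNParams":
        return replace(self, **kwargs)

    def __repr__(self) -> str:
        return (
            f"MMNParams(p={self.p}, n={self.n}, mixing={self.mixing.family!r})"
        )
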