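"""Container for collections of matrix-valued observations."""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np

__all__ = ["MatrixDataset"]


class MatrixDataset:
    """An ordered collection of ``N`` real ``p x n`` observation matrices.

    Stored internally as one ``(N, p, n)`` array.  All observations must
    share the same shape and contain only finite entries.
    """

    def __init__(self, observations: Union[np.ndarray, Sequence[np.ndarray]]):
        if isinstance(observations, np.ndarray) and observations.ndim == 3:
            stacked = np.asarray(observations, dtype=float)
        else:
            mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in observations]
            if not mats:
                raise ValueError("dataset needs at least one observation")
            shape = mats[0].shape
            for k, m in enumerate(mats):
                if m.shape != shape:
                    raise ValueError(
                        f"observation {k} has shape {m.shape}, expected {shape}"
                    )
            stacked = np.stack(mats, axis=0)
        if stacked.ndim != 3 or stacked.shape[0] < 1:
            raise ValueError("observations must form an (N, p, n) stack with N >= 1")
        if not np.all(np.isfinite(stacked)):
            raise ValueError("observations contain non-finite entries")
        self._data = stacked

    # -- basic protocol ---------------------------------------------------

    @property
    def observations(self) -> np.ndarray:
        """The ``(N, p, n)`` stack (a view; do not mutate)."""
        return self._data

    @property
    def N(self) -> int:
        return self._data.shape[0]

    @property
    def p(self) -> int:
        return self._data.shape[1]

    @property
    def n(self) -> int:
        return self._data.shape[2]

    def __len__(self) -> int:
        return self.N

    def __getitem__(self, i) -> np.ndarray:
        return self._data[i]

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self._data)

    def __repr__(self) -> str:
        return f"MatrixDataset(N={self.N}, p={self.p}, n={self.n})"

    def mean(self) -> np.ndarray:
        return self._data.mean(axis=0)

    # -- serialization ----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write one observation per row, row-major flattening.

        The header comment records the matrix shape so the file is
        self-describing:  ``# p=3 n=4``.
        """
        flat = self._data.reshape(self.N, self.p * self.n)
        header = f"p={self.p} n={self.n}"
        np.savetxt(path, flat, delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path, p: int | None = None, n: int | None = None) -> "MatrixDataset":
        """Read a dataset written by :meth:`to_csv`.

        Also accepts whitespace-separated plain text; in that case (or when
        the shape header is absent) ``p`` and ``n`` must be supplied.
        """
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "p=" in first and "n=" in first:
            tokens = dict(
                tok.split("=") for tok in first.lstrip("# ").split() if "=" in tok
            )
            p = int(tokens["p"])
            n = int(tokens["n"])
        if p is None or n is None:
            raise ValueError("matrix shape (p, n) not in header and not supplied")
        try:
            flat = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        except ValueError:
            flat = np.loadtxt(path, comments="#", ndmin=2)
        if flat.shape[1] != p * n:
            raise ValueError(
                f"rows have {flat.shape[1]} values, expected p*n = {p * n}"
            )
        return cls(flat.reshape(-1, p, n))
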