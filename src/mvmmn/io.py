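"""Readers and writers: Statlog satellite text files, dataset CSV round-trips.

The Statlog Landsat format is plain text with 37 whitespace-separated
fields per line: 36 integer spectral attributes (4 bands for each pixel of
a 3x3 neighborhood, pixel-major order) followed by a class label in
1..7.  Each line reshapes to a 4x9 matrix with spectral band as row and
pixel as column.
"""

from __future__ import annotations

from typing import Iterable, Set

import numpy as np

from .dataset import MatrixDataset

__all__ = ["read_statlog", "write_statlog", "STATLOG_CLASSES"]

STATLOG_CLASSES = {
    1: "red soil",
    2: "cotton crop",
    3: "grey soil",
    4: "damp grey soil",
    5: "soil with vegetation stubble",
    7: "very damp grey soil",
}

_N_ATTRS = 36
_N_BANDS = 4
_N_PIXELS = 9


def read_statlog(
    path, class_ids: Iterable[int], transpose: bool = False
) -> MatrixDataset:
    """Read a Statlog satellite file, keeping only the requested classes.

    Each retained line becomes a 4x9 (band x pixel) matrix: column j holds
    attributes 4j-3..4j of the line, i.e. the four spectral values of pixel
    j.  ``transpose=True`` yields 9x4 (pixel x band) matrices instead.
    File order is preserved.
    """
    wanted: Set[int] = set(int(c) for c in class_ids)
    unknown = wanted - set(STATLOG_CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels requested: {sorted(unknown)}")
    mats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != _N_ATTRS + 1:
                raise ValueError(
                    f"line {lineno}: expected {_N_ATTRS + 1} fields, "
                    f"got {len(fields)}"
                )
            label = int(fields[-1])
            if label not in wanted:
                continue
            attrs = np.array([float(v) for v in fields[:-1]])
            mat = attrs.reshape(_N_PIXELS, _N_BANDS).T  # bands x pixels
            mats.append(mat.T if transpose else mat)
    if not mats:
        raise ValueError(f"no observations with classes {sorted(wanted)} in {path}")
    return MatrixDataset(mats)


def write_statlog(path, dataset: MatrixDataset, labels) -> None:
    """Write 4x9 (or transposed 9x4) matrices back to the Statlog text layout."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (dataset.N,):
        raise ValueError("need one class label per observation")
    with open(path, "w") as fh:
        for mat, label in zip(dataset, labels):
            if mat.shape == (_N_PIXELS, _N_BANDS):
                mat = mat.T
            if mat.shape != (_N_BANDS, _N_PIXELS):
                raise ValueError(
                    f"observations must be {_N_BANDS}x{_N_PIXELS} (or transposed), "
                    f"got {mat.shape}"
                )
            attrs = mat.T.reshape(-1)  # pixel-major
            fields = " ".join(str(int(round(v))) for v in attrs)
            fh.write(f"{fields} {int(label)}\n")
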