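"""Correlation-based dissimilarity between cell lines.

The clustering stages all work on d(x_i, x_j) = 1 - corr(x_i, x_j), where
corr is the Pearson coefficient. Unlike Euclidean distance, this is invariant
to positive affine rescaling of a profile, which is what one wants for
microarray log-ratios. It is *not* a metric (no triangle inequality) and no
algorithm in this package assumes it is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric |Omega| x |Omega| matrix of 1 - Pearson correlation values."""

    values: np.ndarray
    space_tag: str = "joint"
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if v.min() < -1e-10 or v.max() > 2 + 1e-10:
            raise ValueError("entries must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str) -> None:
        ids = self.cell_ids or [str(i) for i in range(self.n)]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str, space_tag: str = "joint") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), space_tag=space_tag, cell_ids=[str(c) for c in df.index])


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 minus the Pearson correlation of two profiles, clamped into [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-d vectors of length >= 2")
    for name, v in (("x", x), ("y", y)):
        if np.std(v) == 0.0:
            raise ValueError(f"vector {name} has zero variance; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    corr = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    corr = min(1.0, max(-1.0, corr))
    return 1.0 - corr


def distance_matrix(
    matrix: np.ndarray, space_tag: str = "joint", cell_ids: list[str] | None = None
) -> DistanceMatrix:
    """Pairwise 1 - corr distances between the rows of ``matrix``."""
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    stds = X.std(axis=1)
    bad = np.flatnonzero(stds == 0.0)
    if bad.size:
        name = cell_ids[bad[0]] if cell_ids else str(bad[0])
        raise ValueError(f"cell line {name!r} has a constant profile; correlation undefined")
    corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, space_tag=space_tag, cell_ids=cell_ids)
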