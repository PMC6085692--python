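"""Labelled symmetric distance matrices.

A :class:`DistanceMatrix` is the common currency between the tree, geodesy
and environment layers: an ordered label list plus a symmetric, zero-diagonal,
non-negative matrix. Construction validates the invariants once so downstream
code can rely on them.
"""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "DistanceMatrixError"]


class DistanceMatrixError(ValueError):
    """Raised when a matrix violates distance-matrix invariants."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over a fixed label order.

    Parameters
    ----------
    labels
        Unique row/column labels, in matrix order.
    values
        Square array of distances; must be symmetric (to 1e-12), have an
        exactly zero diagonal, and contain no negative entries.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise DistanceMatrixError(f"matrix must be square, got shape {values.shape}")
        if len(labels) != values.shape[0]:
            raise DistanceMatrixError(
                f"{len(labels)} labels for a {values.shape[0]}x{values.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DistanceMatrixError(f"duplicate labels: {dupes}")
        scale = max(1.0, float(np.abs(values).max()) if values.size else 1.0)
        if not np.allclose(values, values.T, rtol=0.0, atol=1e-12 * scale):
            raise DistanceMatrixError("matrix is not symmetric")
        if np.any(np.diagonal(values) != 0.0):
            raise DistanceMatrixError("diagonal must be exactly zero")
        if np.any(values < 0.0):
            raise DistanceMatrixError("distances must be non-negative")
        values = values.copy()
        values.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(x) for x in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="label")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise DistanceMatrixError("row and column labels differ")
        return cls(tuple(str(x) for x in df.index), df.to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_dataframe(df)
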