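"""Correlation inputs for the network estimators.

Networks here are estimated from a correlation matrix, Spearman by default
because the symptom scores are ordinal.  Rank-based correlation matrices can
be indefinite, and the partial-correlation step requires inversion, so a
positive-semidefinite repair (eigenvalue clipping + rescale to unit diagonal)
is applied automatically and flagged in the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

PSD_EPS = 1e-8


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    method: str            # "spearman" | "pearson"
    n_effective: int
    repaired: bool = False
    names: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(V) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_psd(self, eps: float = PSD_EPS) -> bool:
        return self.min_eigenvalue() >= -eps

    def to_frame(self) -> pd.DataFrame:
        names = list(self.names) if self.names else list(range(self.p))
        return pd.DataFrame(self.values, index=names, columns=names)


def _corr_of_columns(X: np.ndarray, names) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        labels = [names[i] if names else i for i in zero]
        raise ValueError(f"zero-variance column(s): {labels}; correlation undefined")
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def _extract(X):
    """Accept a WaveMatrix or a plain n x p array."""
    data = getattr(X, "data", X)
    names = tuple(getattr(X, "symptom_names", ()))
    return np.asarray(data, dtype=float), names


def spearman_matrix(X) -> CorrelationMatrix:
    """Spearman rank correlation matrix of the columns of ``X``.

    Each column is rank-transformed with average (fractional) ranks for ties,
    then the product-moment correlation of the ranks is taken.
    """
    data, names = _extract(X)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations for a rank correlation")
    ranks = np.column_stack([rankdata(col, method="average") for col in data.T])
    return CorrelationMatrix(_corr_of_columns(ranks, names), "spearman", data.shape[0], names=names)


def pearson_matrix(X) -> CorrelationMatrix:
    """Product-moment correlation matrix of the columns of ``X``."""
    data, names = _extract(X)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations for a correlation")
    return CorrelationMatrix(_corr_of_columns(data, names), "pearson", data.shape[0], names=names)


def nearest_pd(C: CorrelationMatrix, eps: float = PSD_EPS) -> CorrelationMatrix:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Eigenvalues below ``eps`` are raised to ``eps`` and the result is rescaled
    to unit diagonal. PSD inputs are returned unchanged with ``repaired``
    False. Total on symmetric matrices; the output is always PSD.
    """
    w, V = np.linalg.eigh(C.values)
    if w[0] >= eps:
        return C
    w_clipped = np.maximum(w, eps)
    A = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return CorrelationMatrix(A, C.method, C.n_effective, repaired=True, names=C.names)
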