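"""Population structure: principal components of the additive genotype codes
and a line-by-line Pearson similarity matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCResult", "SimilarityMatrix", "pca", "similarity_matrix"]


@dataclass
class PCResult:
    scores: pd.DataFrame            # lines x components
    variance_explained: np.ndarray  # fraction per component, non-increasing

    def __post_init__(self):
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise ValueError("variance_explained entries must lie in [0, 1]")
        if np.any(np.diff(ve) > 1e-10):
            raise ValueError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must sum to at most 1")


@dataclass
class SimilarityMatrix:
    values: pd.DataFrame  # lines x lines Pearson correlations

    def __post_init__(self):
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [-1, 1]")


def pca(Z, n_components: int | None = None) -> PCResult:
    """SVD-based principal components of centered, unit-variance marker
    columns.  Monomorphic (zero-variance) columns are dropped with a warning.
    The explained-variance fraction of component k is s_k^2 / sum(s^2)."""
    Zdf = Z if isinstance(Z, pd.DataFrame) else pd.DataFrame(np.asarray(Z))
    X = Zdf.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two lines")
    if np.isnan(X).any():
        raise ValueError("PCA input must not contain missing codes")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} monomorphic marker column(s) before PCA",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all marker columns are monomorphic")
    X = X[:, keep] / sd[keep]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    ve = s**2 / total
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=Zdf.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCResult(scores=scores, variance_explained=ve[:k])


def similarity_matrix(Z) -> SimilarityMatrix:
    """Pearson correlation of every pair of lines across markers."""
    Zdf = Z if isinstance(Z, pd.DataFrame) else pd.DataFrame(np.asarray(Z))
    X = Zdf.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("similarity needs at least two markers per line")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(Zdf.index[sd == 0])
        raise ValueError(f"constant genotype vector(s), correlation undefined: {bad}")
    C = np.corrcoef(X)
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    vals = pd.DataFrame(C, index=Zdf.index, columns=Zdf.index)
    return SimilarityMatrix(values=vals)
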