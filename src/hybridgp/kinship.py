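"""Genomic relationship matrices from hybrid genotype codes.

``K* = M M^T`` for the code matrix M (additive Z or dominance W), normalized
by the mean of its diagonal so the average self-relationship is 1.  No column
centering by default (a centered variant is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["KinshipMatrix", "additive_kinship", "dominance_kinship", "read_kinship_tsv"]


@dataclass
class KinshipMatrix:
    values: pd.DataFrame
    kind: str                    # "additive" or "dominance"
    normalization_factor: float  # mean of the pre-normalization diagonal

    def __post_init__(self):
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        if not np.isclose(float(np.diag(v).mean()), 1.0, atol=1e-8):
            raise ValueError("mean diagonal must equal 1 after normalization")

    @property
    def line_ids(self) -> list:
        return list(self.values.index)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values.loc[rows, cols].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="line")


def _build(M, kind: str, center: bool) -> KinshipMatrix:
    Mdf = M if isinstance(M, pd.DataFrame) else pd.DataFrame(np.asarray(M, dtype=float))
    X = Mdf.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one marker")
    if np.isnan(X).any():
        raise ValueError("genotype codes must not contain missing values")
    if center:
        X = X - X.mean(axis=0)
    Kstar = X @ X.T
    nf = float(np.diag(Kstar).mean())
    if nf <= 0:
        raise ValueError(f"zero diagonal in raw {kind} kinship (all-zero codes?)")
    K = (Kstar + Kstar.T) / (2.0 * nf)
    vals = pd.DataFrame(K, index=Mdf.index, columns=Mdf.index)
    return KinshipMatrix(values=vals, kind=kind, normalization_factor=nf)


def additive_kinship(Z, center: bool = False) -> KinshipMatrix:
    """Ka = Z Z^T / mean(diag(Z Z^T))."""
    return _build(Z, "additive", center)


def dominance_kinship(W, center: bool = False) -> KinshipMatrix:
    """Kd = W W^T / mean(diag(W W^T))."""
    return _build(W, "dominance", center)


def read_kinship_tsv(path, kind: str = "additive") -> KinshipMatrix:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    vals.columns = vals.index
    return KinshipMatrix(values=vals, kind=kind, normalization_factor=float("nan"))
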