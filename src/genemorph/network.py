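"""Gene co-expression networks and their graph Laplacians.

Nodes are the refined module's genes; edge weights are absolute Pearson
correlations of expression (|r|, so weights are non-negative and the
Laplacian L = D - A is positive semidefinite — the smoothness penalty
g'Lg = 1/2 * sum_ij A_ij (g_i - g_j)^2 requires this). A symmetric-
normalized variant is available behind a flag but off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "correlation_matrix",
    "build_adjacency",
    "laplacian",
]


def correlation_matrix(
    m: ExpressionMatrix, genes: Sequence[str], min_non_na: int = 2
) -> np.ndarray:
    """Pairwise Pearson correlation among ``genes`` (diagonal exactly 1).

    Missing values are tolerated pairwise-complete; a pair with fewer than
    ``min_non_na`` jointly observed samples raises, naming the pair.
    """
    idx = m.gene_indices(genes)
    vals = m.values[idx]
    if np.isnan(vals).any():
        obs = (~np.isnan(vals)).astype(int)
        overlap = obs @ obs.T
        bad = np.argwhere(overlap < min_non_na)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"gene pair ({genes[i]}, {genes[j]}) has only {overlap[i, j]} "
                f"jointly observed samples (< {min_non_na})"
            )
        corr = pd.DataFrame(vals.T).corr(min_periods=min_non_na).to_numpy()
    else:
        corr = np.corrcoef(vals)
    if np.isnan(corr).any():
        bad = [genes[i] for i in np.flatnonzero(np.isnan(corr).any(axis=1))]
        raise ValueError(f"undefined correlation (zero-variance genes?): {bad[:5]}")
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return corr


def build_adjacency(
    corr: np.ndarray, abs_min: float = 0.0, topk_edges: int = 0
) -> np.ndarray:
    """Adjacency from correlations: A_ij = |r_ij| where |r_ij| >= abs_min,
    zero diagonal; optional top-K edge truncation (symmetric pairs counted
    once, ties broken by (-|r|, i, j) for determinism)."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    A = np.abs(corr).copy()
    np.fill_diagonal(A, 0.0)
    A[A < abs_min] = 0.0
    if topk_edges > 0:
        iu, ju = np.triu_indices_from(A, k=1)
        w = A[iu, ju]
        order = np.lexsort((ju, iu, -w))
        keep = order[:topk_edges]
        mask = np.zeros_like(A, dtype=bool)
        mask[iu[keep], ju[keep]] = True
        mask |= mask.T
        A[~mask] = 0.0
    return A


def laplacian(A: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Graph Laplacian L = D - A (or I - D^-1/2 A D^-1/2 if normalized)."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    if np.abs(np.diag(A)).max(initial=0.0) > 0:
        raise ValueError("adjacency must have zero diagonal")
    deg = A.sum(axis=1)
    if not normalized:
        return np.diag(deg) - A
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = np.eye(len(A)) - dinv[:, None] * A * dinv[None, :]
    # isolated nodes contribute empty rows in the normalized form
    L[deg == 0] = 0.0
    L[:, deg == 0] = 0.0
    return L


@dataclass
class CoexpressionNetwork:
    """Correlation network over a fixed ordered gene set, with Laplacian."""

    gene_ids: list[str]
    corr: np.ndarray
    adjacency: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_expression(
        cls,
        m: ExpressionMatrix,
        genes: Sequence[str],
        min_non_na: int = 2,
        abs_min: float = 0.0,
        topk_edges: int = 0,
        normalized_laplacian: bool = False,
    ) -> "CoexpressionNetwork":
        corr = correlation_matrix(m, genes, min_non_na)
        A = build_adjacency(corr, abs_min, topk_edges)
        L = laplacian(A, normalized=normalized_laplacian)
        return cls(list(genes), corr, A, np.diag(A.sum(axis=1)), L)

    @classmethod
    def from_adjacency(cls, gene_ids: Sequence[str], A: np.ndarray) -> "CoexpressionNetwork":
        A = np.asarray(A, dtype=float)
        return cls(list(gene_ids), A.copy(), A, np.diag(A.sum(axis=1)), laplacian(A))

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            {
                "gene_i": [self.gene_ids[i] for i in iu],
                "gene_j": [self.gene_ids[j] for j in ju],
                "weight": self.adjacency[iu, ju],
            }
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_ids": self.gene_ids,
                    "corr": self.corr.tolist(),
                    "adjacency": self.adjacency.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CoexpressionNetwork":
        d = json.loads(Path(path).read_text())
        A = np.asarray(d["adjacency"], dtype=float)
        net = cls.from_adjacency(d["gene_ids"], A)
        net.corr = np.asarray(d["corr"], dtype=float)
        return net
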