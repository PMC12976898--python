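"""Expression matrices: loading, validation and per-gene normalization.

The central container is :class:`ExpressionMatrix`, a thin genes x samples
wrapper used by every downstream stage (labeling, screening, networks).
Values are TPM (non-negative) on load; :func:`zscore_genes` converts to
per-gene z-scores for the screening stages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_tpm", "write_tpm", "zscore_genes", "read_gene_list"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with identifier indexing.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers (rows).
    sample_ids : list of str
        Unique sample identifiers (columns).
    values : ndarray, shape (n_genes, n_samples)
        TPM values (non-negative) when ``normalized`` is False, otherwise
        per-gene z-scores.
    normalized : bool
        Whether :func:`zscore_genes` has been applied.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if not self.normalized and np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("negative values in un-normalized (TPM) matrix")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for ``genes``; raises KeyError naming any absentee."""
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[idx], self.normalized
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool = False) -> "ExpressionMatrix":
        return cls(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(dtype=float),
            normalized,
        )


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_tpm(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited TPM matrix (header = sample IDs, column 1 = gene IDs).

    Duplicate gene rows (e.g. transcript-level rows mapped to one gene
    symbol) are collapsed by summation, mirroring transcript-to-gene TPM
    aggregation. Raises on negative or missing values and on malformed or
    empty files.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cannot parse expression matrix {path}: empty file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"cannot parse expression matrix {path}: no sample columns")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric columns in {path}: {non_numeric[:5]}")
    if df.isna().to_numpy().any():
        raise ValueError(f"missing values in expression matrix {path}")
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).sum()
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative TPM values in {path}")
    return ExpressionMatrix.from_dataframe(df, normalized=False)


def write_tpm(m: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    m.to_dataframe().to_csv(path, sep=sep, index_label="gene_id")


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (population standard deviation).

    Zero-variance genes map to all-zero rows rather than NaN, so that the
    screening Stage 1 filter is the single place such genes are removed.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    if m.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)  # population (divide-by-n)
    centered = m.values - mu
    # constant rows can carry ~1e-16 round-off sd; treat those as zero-variance
    sd_floor = 1e-12 * (np.abs(mu) + 1.0)
    nonconst = sd > sd_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(nonconst, centered / np.where(nonconst, sd, 1.0), 0.0)
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), z, normalized=True)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; ``#`` comments and blank lines ignored."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise ValueError(f"no gene IDs found in {path}")
    return genes
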