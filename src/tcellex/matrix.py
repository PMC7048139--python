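"""Expression-matrix container shared by every pipeline stage.

The matrix is genes x columns (cells for single-cell input, samples for
bulk), carried as a pandas DataFrame together with a *flavor* declaring
the normalization scale of the values:

``log2_tpm10``
    log2(TPM/10 + 1), the full-length single-cell convention.
``centered``
    log-normalized values with a per-patient offset removed; may be
    negative.
``linear_tpm``
    non-negative transcripts-per-million, used for marker gating.
``counts``
    raw integer counts, used for mitochondrial-fraction QC.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FLAVORS = ("log2_tpm10", "centered", "linear_tpm", "counts")

#: flavors whose values are constrained to be non-negative
_NONNEG_FLAVORS = ("log2_tpm10", "linear_tpm", "counts")


class FormatError(ValueError):
    """Malformed expression input (duplicates, non-finite or negative values)."""


@dataclass
class ExpressionMatrix:
    """Genes x columns expression values with a declared normalization flavor.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with cell/sample identifiers
        as columns. Identifiers must be unique and values finite.
    flavor
        One of :data:`FLAVORS`.
    """

    values: pd.DataFrame
    flavor: str = "log2_tpm10"

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}; expected one of {FLAVORS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate column identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if self.flavor in _NONNEG_FLAVORS and (arr < 0).any():
            raise FormatError(f"flavor {self.flavor!r} requires non-negative values")

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        """Column identifiers (cells or bulk samples)."""
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    # -- selection -----------------------------------------------------------
    def require_genes(self, genes: Iterable[str], context: str = "") -> None:
        """Raise ``KeyError`` naming any gene absent from the matrix."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            where = f" ({context})" if context else ""
            raise KeyError(f"gene(s) not present in matrix{where}: {missing}")

    def gene(self, gene: str) -> pd.Series:
        self.require_genes([gene])
        return self.values.loc[gene]

    def subset_cells(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(ids)], self.flavor)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        self.require_genes(genes)
        return ExpressionMatrix(self.values.loc[list(genes)], self.flavor)

    def to_linear(self) -> "ExpressionMatrix":
        """Back-transform to a linear (TPM-like) scale.

        ``log2_tpm10`` inverts exactly to TPM; ``centered`` values are
        exponentiated (2**x), a heuristic since the removed offset is
        unknown; linear flavors pass through.
        """
        if self.flavor == "linear_tpm":
            return self
        if self.flavor == "counts":
            return ExpressionMatrix(self.values, "linear_tpm")
        if self.flavor == "log2_tpm10":
            lin = (np.power(2.0, self.values) - 1.0) * 10.0
        else:  # centered
            lin = np.power(2.0, self.values)
        return ExpressionMatrix(lin, "linear_tpm")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} columns, "
            f"flavor={self.flavor!r})"
        )
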