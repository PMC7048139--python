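"""Text-format readers and writers for expression and clinical tables.

Expression interchange is TSV (first column ``gene``, remaining columns
cell/sample identifiers) or a MatrixMarket coordinate triplet
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``). Clinical tables are
TSV with columns ``sample_id, time, event`` and optional
``tmb, response, dialect, duration``.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as _spio
from scipy import sparse as _spsparse

from .matrix import ExpressionMatrix, FormatError

CLINICAL_REQUIRED = ("sample_id", "time", "event")
CLINICAL_OPTIONAL = ("tmb", "response", "dialect", "duration")


class ParseError(ValueError):
    """Non-numeric or structurally broken cell in a tabular input."""


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "tsv", flavor: str = "log2_tpm10") -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``mtx_triplet`` format.

    For ``mtx_triplet``, ``path`` is the ``.mtx`` file; ``genes.tsv`` and
    ``barcodes.tsv`` (one identifier per line) are read from its directory.
    """
    path = Path(path)
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        raw.index = raw.index.astype(str)
        if raw.index.duplicated().any():
            dups = raw.index[raw.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers in {path.name}: {dups}")
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ParseError(
                f"non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
                f"column {raw.columns[c]!r} in {path.name}"
            )
        if numeric.isna().to_numpy().any():
            raise ParseError(f"missing value(s) in {path.name}")
        return ExpressionMatrix(numeric.astype(float), flavor)
    if format == "mtx_triplet":
        mat = _spio.mmread(path)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        dense = np.asarray(mat.todense() if _spsparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {dense.shape} does not match {len(genes)} genes "
                f"x {len(cells)} barcodes"
            )
        return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=cells), flavor)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx_triplet'")


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        out = m.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")
        return
    if format == "mtx_triplet":
        _spio.mmwrite(str(path), _spsparse.coo_matrix(m.values.to_numpy()))
        pd.Series(m.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(m.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a clinical table in place; returns the table.

    ``event`` is coerced to integers in {0, 1}; ``time`` must be positive.
    Unknown ``dialect`` strings are preserved verbatim so that response
    classification can reject them explicitly.
    """
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample identifiers: {dups}")
    df = df.copy()
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
        bad = df.loc[~(df["time"] > 0), "sample_id"].tolist()
        raise FormatError(f"non-positive survival time for sample(s): {bad}")
    ev = pd.to_numeric(df["event"], errors="raise")
    if not ev.isin([0, 1]).all():
        bad = df.loc[~ev.isin([0, 1]), "sample_id"].tolist()
        raise FormatError(f"event indicator outside {{0,1}} for sample(s): {bad}")
    df["event"] = ev.astype(int)
    for col in ("tmb", "duration"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV; see module docstring for the column contract."""
    df = pd.read_csv(Path(path), sep="\t")
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
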