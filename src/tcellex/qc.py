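"""Cell-quality filters and marker-based T-cell gating.

Two filter families mirror the two normalization flavors: full-length
log2(TPM/10+1) data is filtered on detected-gene count (>= 1700) and mean
housekeeping expression (>= 3); patient-centered data is filtered on a
median - k x MAD detected-gene cut and a mitochondrial count fraction
ceiling (10%). Marker gates on linear TPM select sorted CD8+ (CD3D >= 3,
CD8A >= 3, CD4 <= 30) or CD4+ (CD4 >= 3, CD8A <= 30) T cells.

Boundary semantics follow the removal wording literally: removal
conditions are strict inequalities, so equality at a threshold retains
the cell. The MAD is unscaled (no 1.4826 consistency factor).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class ConfigurationError(ValueError):
    """A required gene list or gate gene is missing or empty."""


@dataclass
class QCReport:
    """Per-cell rule outcomes for one filter application.

    ``per_cell`` holds one boolean *pass* column per applied rule plus a
    composite ``pass_all``; ``thresholds`` records the numeric cutoffs
    actually applied (for the MAD rule, the frozen detected-gene cutoff).
    """

    per_cell: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def retained_ids(self) -> list:
        return self.per_cell.index[self.per_cell["pass_all"]].tolist()

    @property
    def n_retained(self) -> int:
        return int(self.per_cell["pass_all"].sum())

    @property
    def n_removed(self) -> int:
        return len(self.per_cell) - self.n_retained

    def counts_per_rule(self) -> pd.Series:
        """Number of cells failing each individual rule."""
        rules = [c for c in self.per_cell.columns if c != "pass_all"]
        return (~self.per_cell[rules]).sum()


def normalize_log2_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM/10 + 1) transform of a linear-TPM matrix."""
    if m.flavor != "linear_tpm":
        raise ValueError(f"expected flavor 'linear_tpm', got {m.flavor!r}")
    return ExpressionMatrix(np.log2(m.values / 10.0 + 1.0), "log2_tpm10")


def detected_genes(m: ExpressionMatrix) -> pd.Series:
    """Number of genes with any signal (> 0) per cell."""
    return (m.values > 0).sum(axis=0)


def filter_cells_fulllength(
    m: ExpressionMatrix,
    housekeeping: Sequence[str],
    min_genes: int = 1700,
    min_hk: float = 3.0,
) -> Tuple[ExpressionMatrix, QCReport]:
    """Full-length QC: detected-gene floor and housekeeping-mean floor.

    A cell is retained iff it detects at least ``min_genes`` genes AND its
    mean expression over the housekeeping panel is at least ``min_hk``.
    """
    if m.flavor != "log2_tpm10":
        raise ValueError(f"full-length QC expects flavor 'log2_tpm10', got {m.flavor!r}")
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise ConfigurationError("housekeeping gene list is empty")
    m.require_genes(housekeeping, "housekeeping panel")
    det = detected_genes(m)
    hk_mean = m.values.loc[housekeeping].mean(axis=0)
    per_cell = pd.DataFrame(
        {
            "pass_gene_count": det >= min_genes,
            "pass_housekeeping": hk_mean >= min_hk,
        },
        index=m.cell_ids,
    )
    per_cell["pass_all"] = per_cell.all(axis=1)
    report = QCReport(per_cell, {"min_genes": min_genes, "min_hk": min_hk})
    return m.subset_cells(report.retained_ids), report


def filter_cells_mad(
    m: ExpressionMatrix,
    mito_genes: Sequence[str],
    mad_mult: float = 3.0,
    max_mito: float = 0.10,
    counts: Optional[ExpressionMatrix] = None,
    gene_count_cutoff: Optional[float] = None,
) -> Tuple[ExpressionMatrix, QCReport]:
    """MAD-based detected-gene cut plus mitochondrial-fraction ceiling.

    A cell is removed iff its detected-gene count is strictly below
    median - ``mad_mult`` x MAD (MAD unscaled, over all cells) or its
    mitochondrial count fraction is strictly above ``max_mito``. The
    mitochondrial fraction uses raw ``counts`` when supplied, otherwise
    the matrix back-transformed to a linear scale. Passing
    ``gene_count_cutoff`` freezes the threshold instead of recomputing
    median/MAD (used to assert idempotence).
    """
    mito_genes = list(mito_genes)
    if not mito_genes:
        raise ConfigurationError("mitochondrial gene list is empty")
    m.require_genes(mito_genes, "mitochondrial panel")
    if m.n_cells < 3 and gene_count_cutoff is None:
        raise ValueError("median/MAD ill-defined with fewer than 3 cells")
    det = detected_genes(m)
    if gene_count_cutoff is None:
        med = float(np.median(det))
        mad = float(np.median(np.abs(det - med)))
        gene_count_cutoff = med - mad_mult * mad
        source = "recomputed"
    else:
        source = "frozen"
    basis = counts if counts is not None else m.to_linear()
    basis.require_genes(mito_genes, "mitochondrial panel")
    col_tot = basis.values.sum(axis=0)
    mito_tot = basis.values.loc[mito_genes].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = (mito_tot / col_tot).fillna(0.0)
    per_cell = pd.DataFrame(
        {
            "pass_gene_count": ~(det < gene_count_cutoff),
            "pass_mito": ~(mito_frac > max_mito),
        },
        index=m.cell_ids,
    )
    per_cell["pass_all"] = per_cell.all(axis=1)
    report = QCReport(
        per_cell,
        {
            "gene_count_cutoff": float(gene_count_cutoff),
            "max_mito": max_mito,
            "mad_mult": mad_mult,
            "mito_basis": "counts" if counts is not None else "linearized_expression",
            "cutoff_source": source,
        },
    )
    return m.subset_cells(report.retained_ids), report


_GATE_GENES = ("CD3D", "CD8A", "CD4")


def gate_t_cells(
    m: ExpressionMatrix,
    population: str = "CD8",
    cd3d_min: float = 3.0,
    cd8a_min: float = 3.0,
    cd4_max: float = 30.0,
    cd4_min: float = 3.0,
    cd8a_max: float = 30.0,
) -> Tuple[ExpressionMatrix, QCReport]:
    """Marker-threshold gate for sorted T-cell populations on linear TPM.

    CD8 mode keeps cells with CD3D >= 3, CD8A >= 3 and CD4 <= 30; CD4 mode
    keeps cells with CD4 >= 3 and CD8A <= 30 (discard conditions are the
    strict complements, so boundary values are kept).
    """
    if m.flavor not in ("linear_tpm", "counts"):
        raise ValueError(f"gating expects a linear-scale matrix, got flavor {m.flavor!r}")
    missing = [g for g in _GATE_GENES if g not in m.gene_ids]
    if missing:
        raise ConfigurationError(f"gate gene(s) missing from matrix: {missing}")
    cd3d, cd8a, cd4 = (m.values.loc[g] for g in _GATE_GENES)
    if population == "CD8":
        per_cell = pd.DataFrame(
            {
                "pass_cd3d": ~(cd3d < cd3d_min),
                "pass_cd8a": ~(cd8a < cd8a_min),
                "pass_cd4": ~(cd4 > cd4_max),
            },
            index=m.cell_ids,
        )
        thresholds = {"cd3d_min": cd3d_min, "cd8a_min": cd8a_min, "cd4_max": cd4_max}
    elif population == "CD4":
        per_cell = pd.DataFrame(
            {
                "pass_cd4": ~(cd4 < cd4_min),
                "pass_cd8a": ~(cd8a > cd8a_max),
            },
            index=m.cell_ids,
        )
        thresholds = {"cd4_min": cd4_min, "cd8a_max": cd8a_max}
    else:
        raise ValueError(f"population must be 'CD8' or 'CD4', got {population!r}")
    per_cell["pass_all"] = per_cell.all(axis=1)
    thresholds["population"] = population
    report = QCReport(per_cell, thresholds)
    return m.subset_cells(report.retained_ids), report
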