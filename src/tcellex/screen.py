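"""Marker-median subset split, DEG screen, and transcription-factor intersection.

The screen divides cells at the sample median of one marker gene (PDCD1 in
the source analysis), tests every gene between the low and high subsets
with the Wilcoxon rank-sum test, and keeps genes with two-sided P below a
threshold (0.001) whose mean normalized expression clears a flavor-keyed
floor (1 for log2-TPM data, 2 for patient-centered data) in at least one
subset — a gene is filtered out only when it is below the floor in BOTH
subsets. Candidate regulators are the DEGs intersected with a
transcription-factor catalog; candidates shared across datasets are the
final prediction.

No multiple-testing correction enters the DEG decision; a
Benjamini-Hochberg column is emitted for information only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .matrix import ExpressionMatrix
from .stats import EXACT_LIMIT, rank_sum_rows, rank_sum_test

MEAN_FLOORS = {"log2_tpm10": 1.0, "centered": 2.0}


@dataclass
class SubsetSplit:
    """Partition of cells at the sample median of a marker gene."""

    marker: str
    median: float
    labels: pd.Series  # per cell: {low, high, at_median}
    at_median_policy: str

    @property
    def low_ids(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]

    @property
    def high_ids(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def median_split(
    m: ExpressionMatrix, marker: str, at_median: str = "low"
) -> SubsetSplit:
    """Split cells into marker-low/-high subsets at the sample median.

    Cells strictly below the median are low, strictly above are high.
    Cells exactly at the median follow the ``at_median`` policy: ``"low"``
    (default; keeps both subsets populated when the median sits on a mass
    point such as zero-inflated PDCD1) or ``"drop"``.
    """
    if at_median not in ("low", "drop"):
        raise ValueError(f"at_median policy must be 'low' or 'drop', got {at_median!r}")
    vals = m.gene(marker)
    if m.n_cells < 4:
        raise ValueError("median split requires at least 4 cells")
    if vals.nunique() == 1:
        raise ValueError(f"degenerate split: all {marker!r} values identical")
    med = float(np.median(vals.to_numpy()))
    labels = pd.Series("at_median", index=vals.index, dtype=object)
    labels[vals < med] = "low"
    labels[vals > med] = "high"
    if at_median == "low":
        labels[labels == "at_median"] = "low"
    return SubsetSplit(marker, med, labels, at_median)


def screen_degs(
    m: ExpressionMatrix,
    split: SubsetSplit,
    p_threshold: float = 0.001,
    mean_floor: Union[float, str, None] = "auto",
) -> pd.DataFrame:
    """Per-gene rank-sum DEG table between the split subsets.

    Returns a DataFrame indexed by gene with columns ``stat, p, p_bh,
    mean_low, mean_high, direction, pass_p, pass_mean, is_deg``.
    ``mean_floor="auto"`` resolves via the matrix flavor
    (:data:`MEAN_FLOORS`); ``None`` disables the mean filter.
    """
    if not split.labels.index.equals(m.cell_ids):
        if set(split.labels.index) != set(m.cell_ids):
            raise ValueError("split labels do not align with matrix columns")
    labels = split.labels.reindex(m.cell_ids)
    mask_low = (labels == "low").to_numpy()
    mask_high = (labels == "high").to_numpy()
    if mask_low.sum() < 2 or mask_high.sum() < 2:
        raise ValueError(
            f"each subset needs >= 2 cells; got low={int(mask_low.sum())}, "
            f"high={int(mask_high.sum())}"
        )
    if mean_floor == "auto":
        mean_floor = MEAN_FLOORS.get(m.flavor)
        if mean_floor is None:
            raise ValueError(
                f"no default mean floor for flavor {m.flavor!r}; pass one explicitly"
            )

    values = m.values.to_numpy()
    n_pooled = int(mask_low.sum() + mask_high.sum())
    if n_pooled <= EXACT_LIMIT:
        stats_p = [
            rank_sum_test(row[mask_high], row[mask_low]) for row in values
        ]
        stat = np.array([r.statistic for r in stats_p])
        p = np.array([r.pvalue for r in stats_p])
    else:
        stat, p = rank_sum_rows(values, mask_high, mask_low)
    mean_low = values[:, mask_low].mean(axis=1)
    mean_high = values[:, mask_high].mean(axis=1)
    pass_p = p < p_threshold
    if mean_floor is None:
        pass_mean = np.ones(m.n_genes, dtype=bool)
    else:
        pass_mean = np.maximum(mean_low, mean_high) >= mean_floor
    table = pd.DataFrame(
        {
            "stat": stat,
            "p": p,
            "p_bh": _sps.false_discovery_control(p, method="bh"),
            "mean_low": mean_low,
            "mean_high": mean_high,
            "direction": np.where(mean_high >= mean_low, "up_in_high", "up_in_low"),
            "pass_p": pass_p,
            "pass_mean": pass_mean,
        },
        index=m.gene_ids,
    )
    table["is_deg"] = table["pass_p"] & table["pass_mean"]
    return table


def intersect_tfs(degs: pd.DataFrame, tf_catalog: Iterable[str]) -> pd.DataFrame:
    """DEGs that are catalogued transcription factors, ordered by P ascending.

    Returns a ``(gene, p)`` DataFrame (gene as a column, stable P order).
    """
    catalog = set(tf_catalog)
    if not catalog:
        raise ValueError("transcription-factor catalog is empty")
    hits = degs.loc[degs["is_deg"] & degs.index.isin(catalog), ["p"]]
    hits = hits.sort_values("p", kind="stable").reset_index(names="gene")
    return hits[["gene", "p"]]


def cross_dataset_candidates(
    candidate_lists: Sequence[Union[pd.DataFrame, Iterable[str]]],
) -> List[str]:
    """Transcription factors shared by every per-dataset candidate list.

    Accepts the ``(gene, p)`` frames from :func:`intersect_tfs` or plain
    gene iterables. Shared genes are ordered by their maximum P across
    datasets ascending (alphabetically when no P is available).
    """
    if len(candidate_lists) < 2:
        raise ValueError("need candidate lists from at least 2 datasets")
    norm = []
    for cl in candidate_lists:
        if isinstance(cl, pd.DataFrame):
            norm.append(dict(zip(cl["gene"], cl["p"])))
        else:
            norm.append({g: np.nan for g in cl})
    shared = set(norm[0])
    for d in norm[1:]:
        shared &= set(d)
    if not shared:
        return []
    def max_p(g: str) -> float:
        vals = [d[g] for d in norm if not np.isnan(d[g])]
        return max(vals) if vals else np.inf  # no P anywhere -> sort by name

    return sorted(shared, key=lambda g: (max_p(g), g))
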