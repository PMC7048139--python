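"""T-cell state classification, branch enrichment and pseudotime dynamics.

Cells are classified from three markers — CD62L (SELL), CD127 (IL7R) and
PDCD1 — by the rules: effector = all three negative; exhausted = PDCD1
positive; memory = CD62L or CD127 positive. A cell matching two or more
rules is *ambiguous*; a cell matching none is *unknown* (only reachable
when a marker value is missing or an indeterminate band is configured —
under the pure three-rule logic every fully determined cell matches at
least one rule). Branch enrichment is a one-tailed exact binomial test of
each state's count within a branch against its pooled background
frequency; expression dynamics between states or branches use the
one-tailed Mann-Whitney U test. Trajectory reconstruction itself is an
input contract: any (cell, branch, pseudotime) table is accepted.
"""
from __future__ import annotations

from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .matrix import ExpressionMatrix
from .qc import ConfigurationError
from .stats import rank_sum_test

DEFAULT_STATE_MARKERS = {"CD62L": "SELL", "CD127": "IL7R", "PDCD1": "PDCD1"}

CLASSIFIED_STATES = ("effector", "exhausted", "memory")


def call_state(
    m: ExpressionMatrix,
    positivity_threshold: float = 0.0,
    markers: Mapping[str, str] = DEFAULT_STATE_MARKERS,
    indeterminate_band: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Classify each cell as effector / exhausted / memory / ambiguous / unknown.

    A marker is positive when its expression exceeds ``positivity_threshold``
    (default 0: any detection on log-normalized data). With an
    ``indeterminate_band`` (low, high), values strictly inside the band are
    treated as undetermined and the cell becomes *unknown*.

    Returns a DataFrame indexed by cell with boolean columns ``cd62l_pos,
    cd127_pos, pdcd1_pos`` (nullable) and a ``state`` column.
    """
    for role in ("CD62L", "CD127", "PDCD1"):
        if role not in markers:
            raise ConfigurationError(f"no gene configured for marker role {role!r}")
    genes = {role: markers[role] for role in ("CD62L", "CD127", "PDCD1")}
    missing = [g for g in genes.values() if g not in m.gene_ids]
    if missing:
        raise ConfigurationError(f"state marker gene(s) missing from matrix: {missing}")

    def positive(gene: str) -> pd.Series:
        vals = m.values.loc[gene]
        pos = pd.Series(vals > positivity_threshold, dtype="boolean")
        if indeterminate_band is not None:
            lo, hi = indeterminate_band
            pos[(vals > lo) & (vals < hi)] = pd.NA
        return pos

    cd62l = positive(genes["CD62L"])
    cd127 = positive(genes["CD127"])
    pdcd1 = positive(genes["PDCD1"])
    undetermined = cd62l.isna() | cd127.isna() | pdcd1.isna()

    eff = (~cd62l & ~cd127 & ~pdcd1).fillna(False)
    exh = pdcd1.fillna(False)
    mem = (cd62l | cd127).fillna(False)
    n_rules = (
        eff.astype(int) + exh.astype(int) + mem.astype(int)
    )
    state = pd.Series("unknown", index=m.cell_ids, dtype=object)
    state[n_rules >= 2] = "ambiguous"
    state[(n_rules == 1) & eff] = "effector"
    state[(n_rules == 1) & exh] = "exhausted"
    state[(n_rules == 1) & mem] = "memory"
    state[undetermined.to_numpy(dtype=bool)] = "unknown"
    return pd.DataFrame(
        {
            "cd62l_pos": cd62l,
            "cd127_pos": cd127,
            "pdcd1_pos": pdcd1,
            "state": state,
        },
        index=m.cell_ids,
    )


def branch_enrichment(states: pd.Series, branches: pd.Series) -> pd.DataFrame:
    """One-tailed exact binomial enrichment of each state within each branch.

    Ambiguous/unknown cells are excluded. For branch b and state s with
    k of the branch's n classified cells in state s, and pooled background
    frequency p0 of s among all classified cells, P = sum_{j>=k} C(n,j)
    p0^j (1-p0)^(n-j). Branches with no classified cells report P as NaN.
    """
    states = states.reindex(branches.index)
    classified = states.isin(CLASSIFIED_STATES)
    if branches.nunique() < 2:
        raise ValueError("need at least 2 branches")
    pooled = states[classified]
    n_classified = int(classified.sum())
    rows = []
    for state in CLASSIFIED_STATES:
        p0 = float((pooled == state).sum()) / n_classified if n_classified else np.nan
        for branch in sorted(branches.dropna().unique()):
            in_branch = classified & (branches == branch)
            n = int(in_branch.sum())
            k = int((states[in_branch] == state).sum())
            if n == 0 or not 0.0 < p0 < 1.0:
                p = np.nan
            else:
                p = float(_sps.binom.sf(k - 1, n, p0))
            rows.append(
                {"branch": branch, "state": state, "k": k, "n": n, "p0": p0, "p": p}
            )
    return pd.DataFrame(rows)


def dynamics_test(
    m: ExpressionMatrix,
    groups: pd.Series,
    gene: str,
    target: str = "exhausted",
    reference: str = "effector",
) -> float:
    """One-tailed Mann-Whitney P for upregulation of ``gene`` in ``target``.

    ``groups`` maps each cell to a group label (per-cell marker states or
    branch labels); the test asks whether expression in the target group
    is stochastically greater than in the reference group.
    """
    vals = m.gene(gene)
    groups = groups.reindex(m.cell_ids)
    x = vals[(groups == target).to_numpy(dtype=bool)]
    y = vals[(groups == reference).to_numpy(dtype=bool)]
    if x.size == 0 or y.size == 0:
        raise ValueError(
            f"empty comparison group: {target}={x.size} cells, {reference}={y.size} cells"
        )
    return rank_sum_test(x, y, alternative="greater").pvalue


def fit_expression_trend(
    pseudotime,
    expr,
    bandwidth: float = 0.1,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Gaussian-kernel local mean of expression over pseudotime.

    Returns a DataFrame with columns ``pseudotime`` (an even grid spanning
    the observed pseudotime range) and ``expression`` (the
    Nadaraya-Watson estimate). The curve stays within the data range by
    construction (it is a convex combination of observations).
    """
    pt = np.asarray(pseudotime, dtype=float).ravel()
    ex = np.asarray(expr, dtype=float).ravel()
    if pt.size != ex.size:
        raise ValueError("pseudotime and expression must have equal length")
    if pt.size < 10:
        raise ValueError("trend fitting requires at least 10 cells")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(pt.min(), pt.max(), grid_size)
    w = np.exp(-0.5 * ((grid[:, None] - pt[None, :]) / bandwidth) ** 2)
    w_sum = w.sum(axis=1)
    curve = (w @ ex) / np.where(w_sum > 0, w_sum, 1.0)
    return pd.DataFrame({"pseudotime": grid, "expression": curve})
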