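"""Rank statistics underlying the differential-expression screen.

The central primitive is the two-sample Wilcoxon rank-sum (Mann-Whitney U)
test with midranks for ties. Small pooled samples are handled by exhaustive
enumeration of the permutation null (exact even under ties); larger samples
use the normal approximation with tie-corrected variance and a continuity
correction. A vectorized row-wise variant serves genome-scale screens.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal

import numpy as np
from scipy import stats as _sps

Alternative = Literal["two_sided", "greater", "less"]

#: pooled-sample-size boundary below which the exact permutation null is used
EXACT_LIMIT = 12


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  #: Mann-Whitney U for the first sample (ties get 1/2)
    pvalue: float
    exact: bool  #: True when the permutation null was enumerated


def _u_statistic(ranks: np.ndarray, nx: int, ny: int) -> float:
    """U for the first sample from pooled midranks of its members."""
    return float(ranks.sum() - nx * (nx + 1) / 2.0)


def rank_sum_test(
    x, y, alternative: Alternative = "two_sided", exact_limit: int = EXACT_LIMIT
) -> RankSumResult:
    """Wilcoxon rank-sum test of ``x`` versus ``y``.

    ``alternative="greater"`` tests whether ``x`` is stochastically larger
    than ``y``. For pooled sizes up to ``exact_limit`` the permutation
    distribution of U is enumerated exhaustively (valid with ties);
    otherwise the tie-corrected normal approximation with continuity
    correction is used. The returned p-value lies in (0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:nx], nx, ny)

    if n <= exact_limit:
        # Exhaustive permutation null: every assignment of nx pooled values
        # to the first sample is equally likely under H0.
        mu = nx * ny / 2.0
        n_total = comb(n, nx)
        n_ge = n_le = n_extreme = 0
        dev_obs = abs(u_obs - mu)
        for idx in combinations(range(n), nx):
            u = _u_statistic(ranks[list(idx)], nx, ny)
            if u >= u_obs - 1e-9:
                n_ge += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                n_extreme += 1
        if alternative == "greater":
            p = n_ge / n_total
        elif alternative == "less":
            p = n_le / n_total
        else:
            p = n_extreme / n_total
        return RankSumResult(u_obs, min(1.0, p), exact=True)

    # normal approximation, tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    mu = nx * ny / 2.0
    if var <= 0:  # all pooled values identical
        return RankSumResult(u_obs, 1.0, exact=False)
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        p = _sps.norm.sf(z)
    elif alternative == "less":
        z = (u_obs - mu + 0.5) / sd
        p = _sps.norm.cdf(z)
    else:
        z = (abs(u_obs - mu) - 0.5) / sd
        p = 2.0 * _sps.norm.sf(max(z, 0.0))
    p = float(min(1.0, max(p, np.nextafter(0, 1))))
    return RankSumResult(u_obs, p, exact=False)


def rank_sum_rows(values: np.ndarray, mask_x: np.ndarray, mask_y: np.ndarray):
    """Row-wise two-sided rank-sum tests for a genes x cells array.

    Vectorized normal-approximation path used by the DEG screen, where
    group sizes are far above :data:`EXACT_LIMIT`. Returns ``(U, p)``
    arrays, one entry per row.
    """
    values = np.asarray(values, dtype=float)
    mask_x = np.asarray(mask_x, dtype=bool)
    mask_y = np.asarray(mask_y, dtype=bool)
    nx, ny = int(mask_x.sum()), int(mask_y.sum())
    if nx < 2 or ny < 2:
        raise ValueError("each subset must contain at least 2 cells")
    # column order: x block then y block
    cols = np.concatenate([np.where(mask_x)[0], np.where(mask_y)[0]])
    sub = values[:, cols]
    n = nx + ny
    ranks = _sps.rankdata(sub, axis=1)
    u = ranks[:, :nx].sum(axis=1) - nx * (nx + 1) / 2.0

    # per-row tie correction: sum over tied groups of t^3 - t
    srt = np.sort(sub, axis=1)
    new_group = np.ones_like(srt, dtype=bool)
    new_group[:, 1:] = srt[:, 1:] != srt[:, :-1]
    tie_term = np.empty(sub.shape[0])
    for i in range(sub.shape[0]):  # modest loop; inner work is vectorized
        counts = np.diff(np.append(np.where(new_group[i])[0], n))
        tie_term[i] = float((counts.astype(float) ** 3 - counts).sum())

    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / sd
    p = np.where(sd > 0, 2.0 * _sps.norm.sf(np.maximum(z, 0.0)), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return u, p
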