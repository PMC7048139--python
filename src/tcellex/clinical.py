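"""T-cell-normalized scoring of bulk tumors, survival and response analysis.

Bulk TOX expression is normalized to the tumor's T-cell content with the
geometric mean of CD3D/CD3E/CD3G: on the default log scale the score is
log2(TOX + c) minus the mean of log2(CD3x + c) with pseudocount c. Cohorts
are stratified at the top 30% of scores (high vs rest), NSCLC survival
cohorts are pre-filtered to the top 25% tumor mutation burden, groups are
compared with the Kaplan-Meier estimator and the log-rank test, and
anti-PD-1 response is analyzed per cohort dialect with a two-tailed
Mann-Whitney test and an AUROC that ranks patients by ascending score
(low TOX predicts response).

Kaplan-Meier and log-rank statistics are delegated to lifelines; ROC and
AUROC to scikit-learn.
"""
from __future__ import annotations

import math
import warnings
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve

from .matrix import ExpressionMatrix
from .qc import ConfigurationError
from .stats import rank_sum_test

DEFAULT_CD3_TRIO = ("CD3D", "CD3E", "CD3G")

RESPONSE_DIALECTS = ("hugo", "jung", "riaz", "internal")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def tcell_normalized_score(
    m: ExpressionMatrix,
    target: str = "TOX",
    cd3_trio: Sequence[str] = DEFAULT_CD3_TRIO,
    pseudocount: float = 1.0,
    mode: str = "log_diff",
) -> pd.DataFrame:
    """Per-sample target expression normalized to T-cell content.

    ``mode="log_diff"`` (default): log2(target + c) - mean log2(CD3x + c),
    i.e. the log of the pseudocounted target-over-geometric-mean ratio.
    ``mode="linear_ratio"``: the ratio itself. Samples whose three CD3
    values are all zero are scored but flagged ``low_tcell``.

    Returns a DataFrame indexed by sample with columns ``target_value,
    cd3_geomean, score, low_tcell``.
    """
    if m.flavor not in ("linear_tpm", "counts"):
        raise ValueError(
            f"scoring expects linear-scale expression, got flavor {m.flavor!r}"
        )
    if mode not in ("log_diff", "linear_ratio"):
        raise ValueError(f"mode must be 'log_diff' or 'linear_ratio', got {mode!r}")
    genes = [target, *cd3_trio]
    missing = [g for g in genes if g not in m.gene_ids]
    if missing:
        raise ConfigurationError(f"scoring gene(s) missing from matrix: {missing}")
    t = m.values.loc[target]
    cd3 = m.values.loc[list(cd3_trio)]
    log_t = np.log2(t + pseudocount)
    log_cd3_mean = np.log2(cd3 + pseudocount).mean(axis=0)
    log_diff = log_t - log_cd3_mean
    score = log_diff if mode == "log_diff" else np.power(2.0, log_diff)
    return pd.DataFrame(
        {
            "target_value": t,
            "cd3_geomean": np.power(2.0, log_cd3_mean) - pseudocount,
            "score": score,
            "low_tcell": (cd3 == 0).all(axis=0),
        },
        index=m.cell_ids,
    )


def estimate_t_cell_abundance(
    m: ExpressionMatrix,
    cd3_trio: Sequence[str] = DEFAULT_CD3_TRIO,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Pseudocounted geometric mean of the CD3 trio per sample.

    A proxy for tumor-infiltrating T-cell abundance; cohorts whose median
    abundance is low carry unreliable normalized scores.
    """
    missing = [g for g in cd3_trio if g not in m.gene_ids]
    if missing:
        raise ConfigurationError(f"CD3 trio gene(s) missing from matrix: {missing}")
    cd3 = m.values.loc[list(cd3_trio)]
    gm = np.exp(np.log(cd3 + pseudocount).mean(axis=0)) - pseudocount
    gm.name = "tcell_abundance"
    return gm


def low_abundance_warning(
    abundance: pd.Series, floor: Optional[float] = None
) -> Tuple[bool, float]:
    """Advisory check that a cohort has enough T-cell signal to score.

    Returns ``(triggered, floor)``; the default floor is the 25th
    percentile of the supplied abundance distribution.
    """
    if floor is None:
        floor = float(np.percentile(abundance, 25.0))
    triggered = bool(np.median(abundance) < floor)
    if triggered:
        warnings.warn(
            f"cohort median T-cell abundance {np.median(abundance):.3g} is below "
            f"the floor {floor:.3g}; normalized scores may be unreliable",
            stacklevel=2,
        )
    return triggered, floor


def add_waterfall(scores: pd.DataFrame, cohort: Optional[pd.Series] = None) -> pd.DataFrame:
    """Append a ``waterfall`` column: score minus the per-cohort median."""
    out = scores.copy()
    if cohort is None:
        out["waterfall"] = out["score"] - out["score"].median()
    else:
        cohort = cohort.reindex(out.index)
        out["waterfall"] = out["score"] - out.groupby(cohort)["score"].transform("median")
    return out


def stratify_top_fraction(scores: pd.Series, fraction: float = 0.30) -> pd.Series:
    """Label the ceil(fraction * n) highest scores ``high``, the rest ``low``.

    Boundary ties are broken by stable input order (first-seen sample
    wins), with a warning when the boundary is tied.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1); got {fraction}")
    scores = pd.Series(scores)
    n = len(scores)
    if n < 4:
        raise ValueError("stratification requires at least 4 samples")
    n_high = math.ceil(fraction * n)
    order = np.argsort(-scores.to_numpy(), kind="stable")
    vals = scores.to_numpy()
    if n_high < n and vals[order[n_high - 1]] == vals[order[n_high]]:
        warnings.warn(
            "tied scores at the stratification boundary; breaking ties by "
            "stable sample order",
            stacklevel=2,
        )
    labels = pd.Series("low", index=scores.index, dtype=object)
    labels.iloc[order[:n_high]] = "high"
    return labels


def filter_top_tmb(clinical: pd.DataFrame, fraction: float = 0.25) -> pd.DataFrame:
    """Keep the ceil(fraction * n) highest-TMB samples (stable tie-break)."""
    if "tmb" not in clinical.columns or clinical["tmb"].isna().any():
        raise ValueError("tumor mutation burden required for every sample")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1]; got {fraction}")
    n_keep = math.ceil(fraction * len(clinical))
    order = np.argsort(-clinical["tmb"].to_numpy(), kind="stable")
    return clinical.iloc[np.sort(order[:n_keep])]


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_estimate(
    times, events, groups
) -> Dict[str, pd.DataFrame]:
    """Kaplan-Meier curves per group (deaths before censorings at ties).

    Returns, per group label, a DataFrame with columns ``time, at_risk,
    events, survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    curves: Dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        tab = kmf.event_table[kmf.event_table.index > 0]
        curves[str(g)] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
                "events": tab["observed"].to_numpy(),
                "survival": kmf.survival_function_.loc[tab.index, "KM_estimate"].to_numpy(),
            }
        ).reset_index(drop=True)
    return curves


def logrank_test(times, events, groups) -> Dict[str, float]:
    """Log-rank test between survival groups.

    Returns ``{"chi_square", "df", "p"}``. Requires at least one observed
    event and at least two groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if events.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    if pd.unique(groups).size < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return {
        "chi_square": float(res.test_statistic),
        "df": int(res.degrees_of_freedom),
        "p": float(res.p_value),
    }


# ---------------------------------------------------------------------------
# anti-PD-1 response
# ---------------------------------------------------------------------------

_HUGO_MAP = {
    "Complete Response": "responder",
    "Partial Response": "responder",
    "Progressive Disease": "non_responder",
}


def classify_response(clinical: pd.DataFrame, dialect: str) -> pd.Series:
    """Map cohort-specific response annotations to responder labels.

    Dialects: ``hugo`` (PR/CR responder, PD non-responder), ``jung``
    (DCB responder, NDB non-responder), ``riaz`` (as hugo but Stable
    Disease excluded), ``internal`` (PR — or CR — responder; SD responder
    iff duration > 6 months, requiring a ``duration`` column; PD
    non-responder). Unknown annotation strings raise, listing the samples.
    """
    if dialect not in RESPONSE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {RESPONSE_DIALECTS}")
    if "response" not in clinical.columns:
        raise ValueError("clinical table has no 'response' column")
    resp = clinical["response"].astype(str)
    labels = pd.Series(pd.NA, index=clinical.index, dtype=object)
    if dialect in ("hugo", "riaz"):
        mapping = dict(_HUGO_MAP)
        if dialect == "riaz":
            mapping["Stable Disease"] = "excluded"
        labels[:] = resp.map(mapping)
    elif dialect == "jung":
        labels[:] = resp.map({"DCB": "responder", "NDB": "non_responder"})
    else:  # internal
        labels[resp.isin(["PR", "CR"])] = "responder"
        labels[resp == "PD"] = "non_responder"
        sd = resp == "SD"
        if sd.any():
            if "duration" not in clinical.columns or clinical.loc[sd, "duration"].isna().any():
                bad = clinical.loc[
                    sd & (clinical.get("duration", pd.Series(np.nan, index=clinical.index)).isna()),
                    "sample_id",
                ].tolist() if "sample_id" in clinical.columns else clinical.index[sd].tolist()
                raise ValueError(
                    f"internal dialect requires a duration (months) for every "
                    f"stable-disease sample; missing for {bad}"
                )
            dur = clinical.loc[sd, "duration"]
            labels[sd] = np.where(dur > 6.0, "responder", "non_responder")
    if labels.isna().any():
        bad = resp[labels.isna()].unique().tolist()
        raise ValueError(
            f"unrecognized response annotation(s) for dialect {dialect!r}: {bad}"
        )
    return labels


def response_association(
    scores: pd.Series, labels: pd.Series
) -> Dict[str, object]:
    """Responder-vs-non-responder test and responder-retrieval ROC.

    Excluded samples are dropped. The two-tailed Mann-Whitney test
    compares scores between groups; the ROC ranks patients by ascending
    score (predictor = negated score, since low TOX predicts response)
    and the AUROC equals the Mann-Whitney U of the non-responder scores
    divided by n1*n2 (ties get half credit).

    Returns ``{"p", "auroc", "roc", "n_responder", "n_non_responder"}``.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).reindex(scores.index)
    keep = labels.isin(["responder", "non_responder"])
    scores, labels = scores[keep], labels[keep]
    y = (labels == "responder").to_numpy(dtype=int)
    n1, n2 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("need at least one responder and one non-responder")
    s = scores.to_numpy(dtype=float)
    p = rank_sum_test(s[y == 1], s[y == 0], alternative="two_sided").pvalue
    auroc = float(roc_auc_score(y, -s))
    fpr, tpr, thr = roc_curve(y, -s)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return {
        "p": float(p),
        "auroc": auroc,
        "roc": roc,
        "n_responder": n1,
        "n_non_responder": n2,
    }
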