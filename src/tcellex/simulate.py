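"""Synthetic single-cell T-cell datasets and bulk clinical cohorts.

The single-cell generator plants a latent exhaustion program: each cell
carries a state (effector, memory, progenitor_exhausted,
terminal_exhausted), a branch (effector->exhausted or effector->memory), a
pseudotime in [0, 1] and a latent exhaustion level ``e``. Immune-checkpoint
genes (PDCD1, HAVCR2, CTLA4, TIGIT, LAG3) and TOX rise log-linearly with
``e``; TCF7/SELL/IL7R are elevated in memory cells; NR4A1 rises only late
(e > 0.7); NFATC1 is elevated with a mild rise while NFATC2 stays flat;
CD3/CD8A lineage markers, a housekeeping panel, 13 mitochondrial tags and a
block of state-independent null genes complete the panel. Counts are drawn
from a negative binomial with mean-dependent dropout, TPM-normalized over
the panel, and transformed to the requested flavor. A configurable fraction
of planted low-quality cells (sparse detection, inflated mitochondrial
load) exercises the QC stage.

The bulk generator mixes a per-tumor T-cell fraction with a within-T-cell
TOX level, plants an exponential proportional-hazards survival effect and a
logistic anti-PD-1 response effect on the true normalized score, and
returns all truth values for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

STATES = ("effector", "memory", "progenitor_exhausted", "terminal_exhausted")
BRANCHES = ("exhausted", "memory")

IC_GENES = ("PDCD1", "HAVCR2", "CTLA4", "TIGIT", "LAG3")

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)


@dataclass
class GeneProgram:
    """Expression program of one gene on the linear TPM scale.

    ``baseline`` is the mean TPM of an effector cell at exhaustion level 0;
    ``slope`` couples the log-mean to the latent exhaustion level ``e``
    (natural-log scale, so mean = baseline * exp(slope * e));
    ``state_mult`` multiplies the mean per cell state; ``late_onset``
    restricts the exhaustion coupling to e above the given threshold
    (the remaining range is rescaled to [0, 1]).
    """

    baseline: float
    slope: float = 0.0
    state_mult: Dict[str, float] = field(default_factory=dict)
    late_onset: Optional[float] = None
    kind: str = "program"  # {program, planted, null, housekeeping, mito}

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline mean must be >= 0")
        for s in self.state_mult:
            if s not in STATES:
                raise ValueError(f"unknown state {s!r} in state_mult")


@dataclass
class CellProgramSpec:
    """Gene panel plus count-model parameters for the single-cell generator."""

    genes: Dict[str, GeneProgram]
    dispersion: float = 2.0  # negative-binomial size; smaller = noisier
    dropout_rate: float = 0.1  # P(dropout) = exp(-dropout_rate * mean TPM)
    depth: float = 0.5  # expected counts per TPM unit at library factor 1
    library_sigma: float = 0.2  # lognormal sd of per-cell library factor
    n_patients: int = 5
    frac_low_quality: float = 0.06
    lowq_failure_prob: float = 0.75  # per-gene detection failure in bad cells
    lowq_mito_boost: float = 10.0
    memory_branch_exhaustion: float = 0.05  # residual e of memory-state cells

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel is empty")
        if not 0.0 <= self.frac_low_quality < 1.0:
            raise ValueError("frac_low_quality must lie in [0, 1)")
        if not 0.0 <= self.lowq_failure_prob <= 1.0:
            raise ValueError("lowq_failure_prob must lie in [0, 1]")
        if self.dispersion <= 0 or self.depth <= 0:
            raise ValueError("dispersion and depth must be positive")

    @property
    def housekeeping_genes(self) -> List[str]:
        return [g for g, p in self.genes.items() if p.kind == "housekeeping"]

    @property
    def mito_genes(self) -> List[str]:
        return [g for g, p in self.genes.items() if p.kind == "mito"]

    @property
    def planted_genes(self) -> List[str]:
        return [g for g, p in self.genes.items() if p.kind == "planted"]

    @property
    def null_genes(self) -> List[str]:
        return [g for g, p in self.genes.items() if p.kind == "null"]


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated single-cell matrix."""

    cells: pd.DataFrame  # cell_id, patient, state, branch, pseudotime, exhaustion, low_quality
    genes: pd.DataFrame  # gene, kind, baseline, slope
    planted_genes: List[str]
    null_genes: List[str]
    counts: pd.DataFrame  # raw counts, genes x cells


def default_cell_spec(
    n_null_genes: int = 500,
    n_planted_genes: int = 20,
    n_housekeeping: int = 20,
    seed: int = 12345,
) -> CellProgramSpec:
    """Default panel: named program genes + planted/null/housekeeping/mito blocks.

    Null-gene baselines are drawn once from a lognormal (median 3 TPM) with
    a generator-local seed so the panel itself is reproducible and
    independent of the per-dataset seed.
    """
    rng = np.random.default_rng(seed)
    genes: Dict[str, GeneProgram] = {}
    mem = "memory"
    # exhaustion program: checkpoints and TOX rise monotonically with e
    genes["PDCD1"] = GeneProgram(3.0, 2.5, {mem: 0.5})
    genes["HAVCR2"] = GeneProgram(6.0, 2.2, {mem: 0.5})
    genes["CTLA4"] = GeneProgram(5.0, 2.2, {mem: 0.6})
    genes["TIGIT"] = GeneProgram(8.0, 2.0, {mem: 0.6})
    genes["LAG3"] = GeneProgram(5.0, 2.2, {mem: 0.5})
    genes["TOX"] = GeneProgram(40.0, 2.2, {mem: 0.6})
    genes["TOX2"] = GeneProgram(1.5, 1.8)
    # memory program; TCF7 also marks progenitor-exhausted (stem-like) cells
    genes["TCF7"] = GeneProgram(
        10.0, 0.0, {mem: 6.0, "progenitor_exhausted": 2.0, "terminal_exhausted": 0.4}
    )
    genes["SELL"] = GeneProgram(2.0, 0.0, {mem: 20.0})
    genes["IL7R"] = GeneProgram(2.5, 0.0, {mem: 15.0})
    # other regulators: late-rising NR4A1, elevated NFATC1, flat NFATC2
    genes["NR4A1"] = GeneProgram(5.0, 2.5, late_onset=0.7)
    genes["NFATC1"] = GeneProgram(30.0, 1.0)
    genes["NFATC2"] = GeneProgram(25.0, 0.0)
    genes["BATF"] = GeneProgram(10.0, 1.2)
    genes["PRDM1"] = GeneProgram(8.0, 1.2)
    # lineage markers of a sorted CD8+ T-cell population
    genes["CD3D"] = GeneProgram(100.0)
    genes["CD3E"] = GeneProgram(120.0)
    genes["CD3G"] = GeneProgram(80.0)
    genes["CD8A"] = GeneProgram(80.0)
    genes["CD4"] = GeneProgram(0.5)
    for i in range(n_planted_genes):
        genes[f"EXH{i + 1:03d}"] = GeneProgram(40.0, 2.0, kind="planted")
    null_base = np.exp(rng.normal(np.log(3.0), 1.0, size=n_null_genes))
    for i in range(n_null_genes):
        genes[f"NULL{i + 1:04d}"] = GeneProgram(float(null_base[i]), kind="null")
    hk_names = ["ACTB", "GAPDH", "B2M"] + [f"HK{i:02d}" for i in range(4, n_housekeeping + 1)]
    # housekeeping carries the bulk of the transcriptome mass, as in real
    # cells; this keeps TPM renormalization from coupling null genes to the
    # exhaustion program's expression surge
    for g in hk_names[:n_housekeeping]:
        genes[g] = GeneProgram(600.0, kind="housekeeping")
    for g in MITO_GENES:
        genes[g] = GeneProgram(25.0, kind="mito")
    return CellProgramSpec(genes=genes)


def expected_tpm(spec: CellProgramSpec, gene: str, state: str, e: float) -> float:
    """Noise-free expected TPM (before panel renormalization) of one gene."""
    prog = spec.genes[gene]
    mult = prog.state_mult.get(state, 1.0)
    if prog.late_onset is not None:
        e_eff = max(0.0, e - prog.late_onset) / (1.0 - prog.late_onset)
    else:
        e_eff = e
    return prog.baseline * mult * float(np.exp(prog.slope * e_eff))


def _validate_proportions(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(
            "state_proportions must be 4 non-negative values summing to 1 "
            f"(effector, memory, progenitor_exhausted, terminal_exhausted); got {p}"
        )
    return p


def make_tcell_dataset(
    spec: CellProgramSpec,
    n_cells: int,
    state_proportions: Sequence[float] = (0.30, 0.25, 0.20, 0.25),
    flavor: str = "log2_tpm10",
    seed: int = 0,
):
    """Generate a single-cell matrix plus ground truth.

    Returns ``(ExpressionMatrix, SyntheticTruth)``. ``state_proportions``
    follows the order of :data:`STATES`. Flavors: ``log2_tpm10``
    (melanoma-like), ``centered`` (NSCLC-like: log values minus a
    per-patient scalar offset), ``linear_tpm`` or ``counts``.
    """
    props = _validate_proportions(state_proportions)
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    gene_names = list(spec.genes)
    n_genes = len(gene_names)

    # -- latent cell structure ----------------------------------------------
    state_idx = rng.choice(4, size=n_cells, p=props)
    states = np.array(STATES)[state_idx]
    branch = np.where(states == "memory", "memory", "exhausted")
    eff = states == "effector"
    branch[eff] = rng.choice(BRANCHES, size=int(eff.sum()))  # trunk cells split
    pt_lo = np.select(
        [states == "effector", states == "progenitor_exhausted"], [0.0, 1 / 3],
        default=2 / 3,
    )
    pt_lo = np.where(states == "memory", 1 / 3, pt_lo)
    pt_hi = np.select(
        [states == "effector", states == "progenitor_exhausted"], [1 / 3, 2 / 3],
        default=1.0,
    )
    pseudotime = rng.uniform(pt_lo, pt_hi)
    e = np.where(states == "memory", spec.memory_branch_exhaustion, pseudotime)
    patients = np.array([f"P{(i % spec.n_patients) + 1:02d}" for i in range(n_cells)])
    low_quality = rng.random(n_cells) < spec.frac_low_quality

    # -- per-gene, per-cell expected TPM ------------------------------------
    baselines = np.array([spec.genes[g].baseline for g in gene_names])
    slopes = np.array([spec.genes[g].slope for g in gene_names])
    onsets = np.array(
        [-1.0 if spec.genes[g].late_onset is None else spec.genes[g].late_onset
         for g in gene_names]
    )
    mult = np.ones((n_genes, n_cells))
    for gi, g in enumerate(gene_names):
        sm = spec.genes[g].state_mult
        if sm:
            mult[gi] = np.array([sm.get(s, 1.0) for s in states])
    e_eff = np.where(
        onsets[:, None] < 0,
        e[None, :],
        np.maximum(0.0, e[None, :] - onsets[:, None]) / np.maximum(1e-12, 1.0 - onsets[:, None]),
    )
    mu = baselines[:, None] * mult * np.exp(slopes[:, None] * e_eff)
    mito_mask = np.array([spec.genes[g].kind == "mito" for g in gene_names])
    if low_quality.any():
        mu[np.ix_(mito_mask, low_quality)] *= spec.lowq_mito_boost

    # -- counts: negative binomial + mean-dependent dropout ------------------
    lib = np.exp(rng.normal(0.0, spec.library_sigma, size=n_cells))
    mean_counts = mu * (spec.depth * lib)[None, :]
    theta = spec.dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p_nb = theta / (theta + mean_counts)
    counts = np.where(
        mean_counts > 0, rng.negative_binomial(theta, np.minimum(p_nb, 1.0)), 0
    )
    p_drop = np.exp(-spec.dropout_rate * mu)
    counts = np.where(rng.random(mu.shape) < p_drop, 0, counts)
    if low_quality.any():
        fail = rng.random(mu.shape) < spec.lowq_failure_prob
        counts = np.where(fail & low_quality[None, :], 0, counts)

    # -- panel-restricted TPM and flavor transform ---------------------------
    total = counts.sum(axis=0).astype(float)
    scale = float(baselines.sum())  # keeps values on the intended TPM scale
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = np.where(total > 0, counts / total * scale, 0.0)
    cell_ids = [f"C{i + 1:05d}" for i in range(n_cells)]
    if flavor == "counts":
        values = counts.astype(float)
    elif flavor == "linear_tpm":
        values = tpm
    else:
        values = np.log2(tpm / 10.0 + 1.0)
        if flavor == "centered":
            for p in np.unique(patients):
                sel = patients == p
                values[:, sel] = values[:, sel] - values[:, sel].mean()
        elif flavor != "log2_tpm10":
            raise ValueError(f"unknown flavor {flavor!r}")
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_names, columns=cell_ids), flavor
    )

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "patient": patients,
            "state": states,
            "branch": branch,
            "pseudotime": pseudotime,
            "exhaustion": e,
            "low_quality": low_quality,
        }
    )
    genes_df = pd.DataFrame(
        {
            "gene": gene_names,
            "kind": [spec.genes[g].kind for g in gene_names],
            "baseline": baselines,
            "slope": slopes,
        }
    )
    truth = SyntheticTruth(
        cells=cells,
        genes=genes_df,
        planted_genes=spec.planted_genes,
        null_genes=spec.null_genes,
        counts=pd.DataFrame(counts, index=gene_names, columns=cell_ids),
    )
    return matrix, truth


def make_null_tcell_dataset(
    n_genes: int = 2000, n_cells: int = 600, seed: int = 0
) -> ExpressionMatrix:
    """State-free null dataset for p-value calibration.

    Every gene is independent of every other; splitting on any one gene
    leaves the rest exactly null. Baselines are moderate (median 20 TPM,
    low dropout) so rank-sum p-values are not dominated by zero ties.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(20.0), 0.5, size=n_genes))
    theta, depth = 2.0, 0.5
    lib = np.exp(rng.normal(0.0, 0.2, size=n_cells))
    mean_counts = base[:, None] * depth * lib[None, :]
    counts = rng.negative_binomial(theta, theta / (theta + mean_counts))
    p_drop = np.exp(-0.1 * base)[:, None] * np.ones((1, n_cells))
    counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)
    total = counts.sum(axis=0).astype(float)
    tpm = np.where(total > 0, counts / total * base.sum(), 0.0)
    values = np.log2(tpm / 10.0 + 1.0)
    names = [f"NULL{i + 1:04d}" for i in range(n_genes)]
    cols = [f"C{i + 1:05d}" for i in range(n_cells)]
    return ExpressionMatrix(pd.DataFrame(values, index=names, columns=cols), "log2_tpm10")


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Bulk tumor cohort with planted survival and response effects.

    The true per-sample score is the standardized log within-T-cell TOX
    level; the hazard ratio applies per unit of that score in an
    exponential proportional-hazards model, and ``response_slope`` is the
    logistic coefficient linking the score to non-response.
    """

    n_patients: int = 300
    tcell_fraction_alpha: float = 2.0  # Beta(alpha, beta) T-cell fraction
    tcell_fraction_beta: float = 8.0
    tox_log_mean: float = np.log(50.0)  # within-T-cell TOX TPM, lognormal
    tox_log_sigma: float = 0.8
    expression_noise_sigma: float = 0.15
    hazard_ratio: float = 2.5
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.30
    response_slope: float = 1.5
    response_intercept: float = 0.0
    tmb_log_mean: float = np.log(5.0)
    tmb_log_sigma: float = 1.0
    n_filler_genes: int = 20
    dialect: str = "hugo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.tcell_fraction_alpha <= 0 or self.tcell_fraction_beta < 0:
            raise ValueError("T-cell fraction Beta parameters must be positive")


#: mean TPM of the CD3 trio inside the T-cell compartment
_CD3_LEVELS = {"CD3D": 100.0, "CD3E": 120.0, "CD3G": 80.0}


def make_bulk_cohort(spec: CohortSpec):
    """Generate ``(ExpressionMatrix(linear_tpm), clinical DataFrame, truth DataFrame)``.

    Truth columns: ``tcell_fraction``, ``tox_within_t``, ``score`` (the
    standardized log TOX level driving both planted effects) and
    ``responder``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    frac = rng.beta(spec.tcell_fraction_alpha, spec.tcell_fraction_beta, size=n)
    frac = np.clip(frac, 0.005, 1.0)
    log_tox = rng.normal(spec.tox_log_mean, spec.tox_log_sigma, size=n)
    z = (log_tox - spec.tox_log_mean) / spec.tox_log_sigma  # true score, N(0,1)
    tox_within = np.exp(log_tox)

    def noisy(mean):
        return mean * np.exp(rng.normal(0.0, spec.expression_noise_sigma, size=n))

    rows = {"TOX": noisy(frac * tox_within)}
    for g, level in _CD3_LEVELS.items():
        rows[g] = noisy(frac * level)
    filler_base = np.exp(rng.normal(np.log(20.0), 1.0, size=spec.n_filler_genes))
    for i in range(spec.n_filler_genes):
        rows[f"BG{i + 1:03d}"] = noisy(np.full(n, filler_base[i]))
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(rows, index=sample_ids).T, "linear_tpm"
    )

    # survival: exponential proportional hazards on the true score
    hazard = spec.baseline_hazard * np.power(spec.hazard_ratio, z)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        cens_hazard = spec.baseline_hazard * spec.censoring_rate / (1.0 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / cens_hazard, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    # response: logistic link, higher score -> less likely to respond
    logit = spec.response_intercept - spec.response_slope * z
    responder = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    response = _dialect_labels(responder, spec.dialect, rng)
    tmb = np.exp(rng.normal(spec.tmb_log_mean, spec.tmb_log_sigma, size=n))

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "tmb": tmb,
            "response": response,
            "dialect": spec.dialect,
            "duration": np.where(responder, 9.0, 3.0),  # months, used by 'internal'
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tcell_fraction": frac,
            "tox_within_t": tox_within,
            "score": z,
            "responder": responder,
        }
    )
    return matrix, clinical, truth


def _dialect_labels(responder: np.ndarray, dialect: str, rng: np.random.Generator):
    if dialect == "hugo":
        pos = np.where(rng.random(responder.size) < 0.5, "Partial Response", "Complete Response")
        return np.where(responder, pos, "Progressive Disease")
    if dialect == "jung":
        return np.where(responder, "DCB", "NDB")
    if dialect == "riaz":
        pos = np.where(rng.random(responder.size) < 0.5, "Partial Response", "Complete Response")
        lab = np.where(responder, pos, "Progressive Disease")
        # sprinkle stable-disease annotations that the classifier must exclude
        sd = rng.random(responder.size) < 0.15
        lab = lab.astype(object)
        lab[sd] = "Stable Disease"
        return lab
    if dialect == "internal":
        return np.where(responder, "PR", np.where(rng.random(responder.size) < 0.5, "PD", "SD"))
    raise ValueError(f"unknown response dialect {dialect!r}")


def slope_for_auroc(target_auroc: float, intercept: float = 0.0) -> float:
    """Logistic slope giving a desired true AUROC under the cohort model.

    With score z ~ N(0,1) and P(responder | z) = sigmoid(intercept - a z),
    the AUROC of the predictor -z for retrieving responders is a smooth,
    increasing function of ``a``; this inverts it by bisection on a
    quadrature grid.
    """
    if not 0.5 <= target_auroc < 1.0:
        raise ValueError("target AUROC must lie in [0.5, 1)")
    grid = np.linspace(-8.0, 8.0, 4001)
    phi = np.exp(-0.5 * grid**2)
    phi /= phi.sum()

    def auroc(a: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(intercept - a * grid)))
        w_r = phi * p
        w_n = phi * (1.0 - p)
        # predictor -z: responder ranked above non-responder when z_r < z_n
        cum_r = np.cumsum(w_r) - w_r  # mass of responders strictly below
        return float((w_n * (cum_r + 0.5 * w_r)).sum() / (w_r.sum() * w_n.sum()))

    lo, hi = 0.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if auroc(mid) < target_auroc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
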