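# Methods

## Scope and data model

The package operates on a genes × columns expression matrix with a declared
normalization *flavor*: `log2_tpm10` (E = log2(TPM/10 + 1), full-length
single-cell data), `centered` (log-normalized values with a per-patient
offset removed, possibly negative), `linear_tpm` (marker gating, bulk
scoring) and `counts` (mitochondrial QC). Trajectory reconstruction is
deliberately an input contract — any (cell, branch, pseudotime) table is
accepted, supplied in practice by the synthetic generator's ground truth —
so no pseudotime inference is performed here.

## Quality control and gating

Full-length data: a cell is retained iff it detects ≥ `min_genes` genes
(a gene is detected when its value is > 0) and its mean expression over a
configurable housekeeping panel is ≥ `min_hk` (defaults 1700 and 3, the
published constants; the housekeeping list itself is configuration, since
no canonical list ships with the package). Centered data: a cell is removed
iff its detected-gene count falls strictly below median − `mad_mult` × MAD
(default 3; MAD unscaled, no 1.4826 consistency factor — the rule is
applied exactly as printed) or its mitochondrial count fraction strictly
exceeds `max_mito` (default 10%), computed on raw counts when available and
on linearized expression otherwise (logged in the report). All removal
conditions are strict inequalities, so equality at a threshold retains the
cell. The MAD cutoff is frozen in the report; idempotence holds against the
frozen cutoff, since recomputing median/MAD on a filtered population would
drift. Marker gates on linear TPM: CD8 mode keeps CD3D ≥ 3 ∧ CD8A ≥ 3 ∧
CD4 ≤ 30; CD4 mode keeps CD4 ≥ 3 ∧ CD8A ≤ 30.

## The rank-sum engine

The Wilcoxon rank-sum test is implemented in-package because the screen
needs exact behavior under heavy ties (zero-inflated markers). Midranks are
used throughout. For pooled n ≤ 12 the permutation null of the
Mann-Whitney U is enumerated exhaustively (all C(n, n₁) assignments), which
is exact even with ties; two-sided p-values count assignments with
|U − n₁n₂/2| at least as large as observed. Above the boundary, the normal
approximation is used with tie-corrected variance
n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))] and a 0.5 continuity correction;
degenerate pooled samples return P = 1. The switch point 12 keeps
enumeration cheap (≤ 924 assignments) while the approximation is standard
above it; oracle tests pin both regimes. The genome-scale screen path
vectorizes ranking and tie correction row-wise and is verified against the
scalar path.

## Subset split and DEG filters

Cells strictly below the sample median of the split marker are *low*,
strictly above *high*. Cells exactly at the median — common when the
median sits on the zero mass of PDCD1 — are assigned to *low* by default
(keeping both subsets non-empty); a `drop` policy is available, and the
choice is recorded per run. A gene is a DEG iff its two-sided P < 0.001
and its mean expression is ≥ the flavor-keyed floor (1 for `log2_tpm10`,
2 for `centered`) in at least one subset: the mean filter removes a gene
only when it is dim in *both* subsets. No multiple-testing correction
enters the decision (the published rule filters on raw P);
Benjamini-Hochberg values are emitted for information. Candidate
regulators are DEGs ∩ TF catalog ordered by P; the cross-dataset
prediction is the set intersection ordered by worst-case P.

## State calling and dynamics statistics

Markers CD62L (SELL), CD127 (IL7R) and PDCD1 are called positive above a
threshold (default 0, i.e. any detection on log-normalized data — the
numeric gate of the original classifier is not recoverable, so detection is
the neutral choice). Rules: effector = all three negative; exhausted =
PDCD1⁺; memory = CD62L⁺ ∨ CD127⁺. Two or more matching rules → ambiguous.
Under this pure logic every determined cell matches ≥ 1 rule, so *unknown*
is reachable only via missing marker values or an optional indeterminate
band (disabled by default). Branch enrichment uses the exact upper binomial
tail with the pooled classified-cell frequency as background — a one-tailed
"enriched" test; ambiguous/unknown cells enter neither k nor n. Group
contrasts delegate to the rank-sum engine with `alternative="greater"`, and
groups may be per-cell marker states or branch labels (both supported;
state labels are the package default in examples). Trend curves are
Nadaraya-Watson Gaussian-kernel means on an even pseudotime grid; the
estimate is a convex combination of observations and therefore stays within
the data range.

## Clinical scoring

The T-cell-normalized score is the log-scale difference
log2(target + c) − mean log2(CD3x + c) with pseudocount c = 1 (config-
exposed; a `linear_ratio` mode exponentiates the same quantity). The
log-difference form was chosen over a linear ratio for additivity and
robustness to zeros; with c → 0 it recovers the exact log ratio on positive
data. Samples with an all-zero CD3 trio are scored but flagged. Cohort
stratification labels the ⌈0.30 n⌉ highest scores *high*; boundary ties
break by stable input order with a warning (no published tie rule exists).
NSCLC survival cohorts are pre-filtered to the ⌈0.25 n⌉ highest tumor
mutation burden. Kaplan-Meier curves and the log-rank test are delegated
to lifelines (deaths processed before censorings at tied times); the
log-rank statistic is pinned in tests to an independently hand-computed
observed/expected/variance table. Response dialects are explicit
enumerations (hugo: PR/CR vs PD; jung: DCB vs NDB; riaz: hugo with Stable
Disease excluded; internal: PR — and CR — responders, SD responders iff
duration > 6 months, requiring a duration column). Unknown annotation
strings fail loudly rather than being guessed. The responder-retrieval ROC
uses the negated score as predictor (low TOX ⇒ predicted responder);
AUROC (scikit-learn) equals the pair-counting statistic U/(n₁n₂) with half
credit for ties, which tests assert directly. A cohort-level advisory warns
when median CD3-trio abundance falls below a floor (default: the 25th
percentile of the pooled distribution), since T-cell-poor cohorts carry
unreliable normalized scores.

## Synthetic data generator

**Single cells.** Each cell draws a state (effector, memory,
progenitor-exhausted, terminal-exhausted; default proportions
0.30/0.25/0.20/0.25), a branch (memory cells on the memory branch,
exhausted on the exhausted branch, effector cells split evenly as the
shared trunk), a pseudotime uniform within state-specific intervals
(effector [0, ⅓], progenitor [⅓, ⅔], terminal [⅔, 1], memory [⅓, 1]) and a
latent exhaustion level e (= pseudotime on the exhausted branch, a residual
0.05 for memory cells). Gene means on the linear TPM scale follow
μ = baseline · state-multiplier · exp(slope · e); checkpoints and TOX carry
slopes 2.0–2.5 (natural log) with baselines 3–40 TPM, NR4A1's slope
activates only above e = 0.7, NFATC1 is elevated with a mild slope, NFATC2
flat, TCF7/SELL/IL7R memory-multiplied, CD3/CD8A flat lineage anchors, and
20 planted exhaustion-coupled genes (baseline 40, slope 2.0) plus 500
state-independent null genes (lognormal baselines, median 3 TPM) and 13
mitochondrial tags complete the panel. Counts are negative binomial
(dispersion θ = 2) around μ × depth × lognormal library factor, thinned by
mean-dependent dropout P = exp(−0.1 μ), then normalized to panel-restricted
TPM (scaled to the panel's baseline mass so values stay on the intended TPM
scale) and transformed to the requested flavor. The housekeeping panel
(20 genes at 600 TPM) deliberately dominates the transcriptome mass so that
TPM renormalization does not couple null genes to the exhaustion program's
expression surge — without that anchoring the nulls are measurably
non-null under the split. A 6% low-quality fraction (75% per-gene detection
failure, 10× mitochondrial boost) carries truth labels for QC tests. The
`centered` flavor subtracts a per-patient scalar offset (the patient grand
mean) from the log values: scalar centering preserves gene-level means so
the mean-expression floor of 2 remains a meaningful filter, which per-gene
centering would render vacuous.

**Bulk cohorts.** Each tumor draws a T-cell fraction f ~ Beta(2, 8) and a
within-T-cell TOX level lognormal(log 50, 0.8); TOX and CD3 trio expression
are f × level with 15% lognormal noise. The true score z standardizes the
log TOX level. Survival is exponential proportional hazards with hazard
0.01 · HR^z (default HR 2.5) and independent exponential censoring tuned to
a 30% rate; response is Bernoulli with logit = intercept − slope · z,
emitted in the requested dialect's annotation strings. A quadrature-based
helper inverts the slope → true-AUROC map so cohorts with a prescribed
discriminability (e.g. AUROC 0.8) can be generated.

**What the generator does not emulate.** No batch effects, doublets,
patient-specific programs, per-gene patient centering, or fitting to any
real dataset's moments. Passing tests therefore demonstrate correct
recovery of the planted statistical structure under a realistic
zero-inflated count model — not performance on real tumor data, where
effect sizes, confounding and annotation noise are harsher.

## Problem sizes and test design

Defaults chosen for the simulation studies: 1000 cells × ~570 genes and 20
seeds for screen recovery (sensitivity and false-positive rates are means
over seeds), 2000 null genes × 600 cells for calibration (DEG count checked
against the 99% binomial interval at rate 0.001, p-values against a
Kolmogorov-Smirnov uniformity check), 300-patient cohorts over 100 seeds
for log-rank detection and 200-patient cohorts over 20 seeds for AUROC
recovery. Exact-statistic oracles (permutation enumeration, binomial
summation, pair counting, a hand-computed log-rank table) run on small
instances where enumeration is feasible. QC thresholds in tests are scaled
to the synthetic panel (min_genes = 150 for ~570 genes); the `paper`
configuration profile retains the full-transcriptome constants (1700, 3,
3×MAD, 10%) for real-data use.

## Known limitations

The NSCLC-flavor mean floor operates on as-provided (centered) values,
whose absolute scale depends on the centering convention; screens on data
centered per gene require an explicitly chosen floor. The binomial branch
test treats cells as independent draws (as the original analysis does),
ignoring the finite-population correction a hypergeometric model would add.
The unscaled median − 3×MAD rule sits near median − 2σ for roughly Gaussian
detected-gene distributions and so intrinsically removes ~2% of good cells;
this is a property of the published rule, not of the implementation.
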