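# tcellex

Analysis pipeline for predicting transcriptional regulators of
tumor-infiltrating CD8+ T cell exhaustion from single-cell transcriptomes,
characterizing expression dynamics across effector / memory / exhausted
states, and scoring bulk tumors by T-cell-normalized *TOX* expression for
survival stratification and anti-PD-1 response prediction. A synthetic-data
module generates all inputs with planted ground truth, so every stage is
testable without downloading any cohort.

## Who this is for

Computational immunologists and tumor-immunology analysts who want a
tested, scriptable implementation of the marker-gated in-silico subset
strategy: instead of clustering, cells are partitioned at the sample median
of a single checkpoint marker and screened for co-regulated genes.

## The method

**Regulator screen.** CD8+ T cells (gated on linear TPM: CD3D ≥ 3,
CD8A ≥ 3, CD4 ≤ 30, after per-cell quality filters) are split at the sample
median of *E*<sub>PDCD1</sub>, where *E* = log2(TPM/10 + 1) for full-length
data or patient-centered normalized expression. Every gene is tested
between PDCD1-low and PDCD1-high subsets with the Wilcoxon rank-sum test
(midranks; exact permutation null for pooled n ≤ 12, tie-corrected normal
approximation with continuity correction above). A gene is a DEG when its
two-sided *P* < 0.001 and its mean expression reaches a flavor-keyed floor
(1 for log2-TPM data, 2 for centered data) in at least one subset. DEGs are
intersected with a transcription-factor catalog, and the TFs shared across
datasets are the predicted regulators.

**Exhaustion dynamics.** Cells are classified by marker rules — effector
(CD62L⁻, CD127⁻, PD-1⁻), exhausted (PD-1⁺), memory (CD62L⁺ or CD127⁺);
multiple matches → ambiguous. Given any (cell, branch, pseudotime) table,
each branch is tested for enrichment of its state with an exact one-tailed
binomial test against the pooled state frequency, and per-gene contrasts
(exhausted vs effector, memory vs effector) use the one-tailed Mann-Whitney
*U* test.

**Clinical scoring.** For bulk tumors, the per-T-cell *TOX* level is
estimated as

&nbsp;&nbsp;&nbsp;&nbsp;score = log2(TOX + 1) − (1/3) Σ<sub>g ∈ {CD3D, CD3E, CD3G}</sub> log2(g + 1),

the log of *TOX* over the geometric mean of the CD3 trio. Patients in the
top 30% of scores (TOX-high) are compared with the rest by Kaplan-Meier
curves and the log-rank test (NSCLC cohorts are first restricted to the top
25% tumor mutation burden); anti-PD-1 cohorts are parsed per response
dialect, compared with a two-tailed Mann-Whitney test, and ranked by
ascending score for responder-retrieval AUROC.

## Worked example

```sh
python examples/01_regulator_screen.py
```

```
[log2_tpm10] median PDCD1 = 0.000, low/high = 592/408 cells
[log2_tpm10] DEGs: 29 (recovered 20/20 planted genes); candidate TFs: TOX, TCF7, BATF, NFATC1
[centered] median PDCD1 = -0.555, low/high = 573/427 cells
[centered] DEGs: 23 (recovered 20/20 planted genes); candidate TFs: TOX
TFs shared by both datasets: ['TOX']
```

The generator plants 20 exhaustion-coupled genes plus the canonical
program (checkpoint genes rising with the latent exhaustion level, *TOX*
among the TFs). The screen recovers all planted genes in both
normalization flavors, and intersecting the per-dataset candidate TFs
leaves *TOX* as the single shared regulator — the pipeline's prediction.
Note the zero-inflated PDCD1 median (0.000): cells exactly at the median
are assigned to the low subset (configurable policy).

`examples/02_exhaustion_dynamics.py` prints the branch-enrichment table
(e.g. exhausted state in the exhausted branch: *P* = 2.4e−19) and per-gene
contrasts (*TOX* one-tailed *P* = 4.0e−16; flat *NFATC2*: *P* = 0.985).
`examples/03_clinical_scoring.py` prints the survival split
(chi-square = 65.0, *P* = 7.5e−16 at planted hazard ratio 2.5) and
responder retrieval (AUROC = 0.824 with planted AUROC 0.8).

A `tcellex` CLI mirrors the library (`simulate`, `qc`, `screen`,
`dynamics`, `score`, `survival`, `response`); every run writes its resolved
configuration next to its outputs.

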