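"""Score bulk tumors by T-cell-normalized TOX and test its clinical value.

Generates a synthetic bulk cohort with a planted hazard effect (hazard
ratio 2.5 per score unit) and a planted anti-PD-1 response effect,
normalizes TOX to the CD3D/CD3E/CD3G geometric mean, stratifies patients
at the top 30% of scores, compares survival with the log-rank test, and
evaluates responder retrieval by ascending score (two-tailed Mann-Whitney
and AUROC).
"""
import tcellex as tx

cohort = tx.CohortSpec(n_patients=300, hazard_ratio=2.5, censoring_rate=0.30,
                       response_slope=tx.slope_for_auroc(0.8), seed=3)
matrix, clinical, truth = tx.make_bulk_cohort(cohort)

scores = tx.tcell_normalized_score(matrix)  # log2(TOX+1) - mean log2(CD3x+1)
scores = tx.add_waterfall(scores)
corr = scores["score"].corr(truth.set_index("sample_id")["score"])
print(f"estimated vs true score correlation: r = {corr:.3f}")

abundance = tx.estimate_t_cell_abundance(matrix)
print(f"median T-cell abundance (CD3 geometric mean): {abundance.median():.1f} TPM")

strata = tx.stratify_top_fraction(scores["score"], fraction=0.30)
res = tx.logrank_test(clinical["time"], clinical["event"], strata.to_numpy())
print(f"TOX-high (top 30%) vs TOX-low survival: "
      f"chi-square = {res['chi_square']:.2f}, P = {res['p']:.2e}")
# Small P: high TOX in the T-cell compartment predicts worse survival.

labels = tx.classify_response(clinical, "hugo")
labels.index = scores.index
resp = tx.response_association(scores["score"], labels)
print(f"responders vs non-responders: Mann-Whitney P = {resp['p']:.2e}, "
      f"AUROC = {resp['auroc']:.3f} "
      f"({resp['n_responder']} responders / {resp['n_non_responder']} non-responders)")
# AUROC near the planted 0.8: ranking patients by ascending normalized TOX
# retrieves anti-PD-1 responders.
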