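"""T-cell-normalized scoring, stratification, survival and response analysis."""
import numpy as np
import pandas as pd
import pytest

import tcellex as tx
from tcellex.qc import ConfigurationError


def bulk_matrix(cols):
    """cols: {sample: {gene: value}} -> linear-TPM matrix."""
    df = pd.DataFrame(cols, dtype=float)
    return tx.ExpressionMatrix(df, "linear_tpm")


class TestScore:
    def test_exact_log_ratio_without_pseudocount(self):
        m = bulk_matrix({"s1": {"TOX": 8, "CD3D": 2, "CD3E": 4, "CD3G": 8}})
        t = tx.tcell_normalized_score(m, pseudocount=0.0)
        assert t.loc["s1", "cd3_geomean"] == pytest.approx(4.0)
        assert t.loc["s1", "score"] == pytest.approx(1.0)  # log2(8/4)

    def test_target_equal_to_trio_scores_zero(self):
        m = bulk_matrix({"s1": {"TOX": 5, "CD3D": 5, "CD3E": 5, "CD3G": 5}})
        assert tx.tcell_normalized_score(m, pseudocount=0.0).loc["s1", "score"] == 0.0

    def test_scale_invariance_without_pseudocount(self):
        base = {"TOX": 8, "CD3D": 2, "CD3E": 4, "CD3G": 8}
        m = bulk_matrix({"s1": base, "s2": {g: 13 * v for g, v in base.items()}})
        t = tx.tcell_normalized_score(m, pseudocount=0.0)
        assert t.loc["s1", "score"] == pytest.approx(t.loc["s2", "score"])

    def test_linear_ratio_mode_matches_exponentiated_log_diff(self):
        m = bulk_matrix({"s1": {"TOX": 8, "CD3D": 2, "CD3E": 4, "CD3G": 8}})
        log_d = tx.tcell_normalized_score(m).loc["s1", "score"]
        ratio = tx.tcell_normalized_score(m, mode="linear_ratio").loc["s1", "score"]
        assert ratio == pytest.approx(2.0 ** log_d)

    def test_zero_cd3_sample_flagged_low_tcell(self):
        m = bulk_matrix(
            {
                "s1": {"TOX": 8, "CD3D": 0, "CD3E": 0, "CD3G": 0},
                "s2": {"TOX": 8, "CD3D": 1, "CD3E": 1, "CD3G": 1},
            }
        )
        t = tx.tcell_normalized_score(m)
        assert bool(t.loc["s1", "low_tcell"]) and not bool(t.loc["s2", "low_tcell"])

    def test_missing_gene_raises(self):
        m = bulk_matrix({"s1": {"TOX": 8, "CD3D": 2, "CD3E": 4}})
        with pytest.raises(ConfigurationError, match="CD3G"):
            tx.tcell_normalized_score(m)

    def test_pseudocount_limit_recovers_log_ratio(self):
        m = bulk_matrix({"s1": {"TOX": 12, "CD3D": 3, "CD3E": 6, "CD3G": 12}})
        exact = tx.tcell_normalized_score(m, pseudocount=0.0).loc["s1", "score"]
        near = tx.tcell_normalized_score(m, pseudocount=1e-9).loc["s1", "score"]
        assert near == pytest.approx(exact, abs=1e-6)


class TestAbundance:
    def test_geometric_mean_examples(self):
        m = bulk_matrix(
            {
                "s1": {"TOX": 1, "CD3D": 1, "CD3E": 1, "CD3G": 1},
                "s2": {"TOX": 1, "CD3D": 2, "CD3E": 4, "CD3G": 8},
            }
        )
        ab = tx.estimate_t_cell_abundance(m, pseudocount=0.0)
        assert ab["s1"] == pytest.approx(1.0)
        assert ab["s2"] == pytest.approx(4.0)

    def test_warning_triggers_below_floor(self):
        ab = pd.Series([0.1, 0.2, 0.3, 5.0])
        from tcellex.clinical import low_abundance_warning

        with pytest.warns(UserWarning, match="abundance"):
            triggered, floor = low_abundance_warning(ab, floor=1.0)
        assert triggered
        ok, _ = low_abundance_warning(ab, floor=0.01)
        assert not ok


class TestStratification:
    def test_top_fraction_counts(self):
        s = pd.Series(np.arange(10, dtype=float))
        labels = tx.stratify_top_fraction(s, 0.3)
        assert (labels == "high").sum() == 3
        assert set(s[labels == "high"]) == {7.0, 8.0, 9.0}
        assert (tx.stratify_top_fraction(pd.Series(np.arange(7.0)), 0.5) == "high").sum() == 4

    def test_all_tied_uses_stable_order_with_warning(self):
        s = pd.Series([2.0] * 10, index=[f"s{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="tied"):
            labels = tx.stratify_top_fraction(s, 0.3)
        assert list(labels[labels == "high"].index) == ["s0", "s1", "s2"]

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            tx.stratify_top_fraction(pd.Series([1.0, 2.0, 3.0]), 0.3)

    def test_waterfall_median_zero_per_cohort(self, bulk_cohort):
        m, clin, _ = bulk_cohort
        scores = tx.tcell_normalized_score(m)
        cohort = pd.Series(
            np.where(np.arange(len(scores)) % 2 == 0, "A", "B"), index=scores.index
        )
        wf = tx.add_waterfall(scores, cohort)
        for _, grp in wf.groupby(cohort):
            assert grp["waterfall"].median() == pytest.approx(0.0, abs=1e-12)


class TestTmbFilter:
    def test_top_quarter(self):
        clin = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(8)],
             "time": 1.0, "event": 1, "tmb": np.arange(8, dtype=float)}
        )
        kept = tx.filter_top_tmb(clin, 0.25)
        assert set(kept["sample_id"]) == {"s6", "s7"}
        assert len(tx.filter_top_tmb(clin, 1.0)) == 8

    def test_boundary_ties_stable(self):
        clin = pd.DataFrame(
            {"sample_id": ["a", "b", "c", "d"], "time": 1.0, "event": 1,
             "tmb": [5.0, 5.0, 5.0, 1.0]}
        )
        kept = tx.filter_top_tmb(clin, 0.25)
        assert list(kept["sample_id"]) == ["a"]

    def test_missing_tmb_raises(self):
        clin = pd.DataFrame({"sample_id": ["a"], "time": 1.0, "event": 1})
        with pytest.raises(ValueError, match="mutation burden"):
            tx.filter_top_tmb(clin)


class TestSurvival:
    def test_km_with_censoring(self):
        curves = tx.km_estimate([1.0, 2.0], [1, 0], ["g", "g"])
        g = curves["g"].set_index("time")
        assert g.loc[1.0, "survival"] == pytest.approx(0.5)
        assert g.loc[2.0, "survival"] == pytest.approx(0.5)

    def test_km_no_events_is_flat_one(self):
        curves = tx.km_estimate([1.0, 2.0, 3.0], [0, 0, 0], ["g"] * 3)
        assert np.allclose(curves["g"]["survival"], 1.0)

    def test_km_all_events_steps(self):
        curves = tx.km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["g"] * 4)
        assert list(curves["g"]["survival"]) == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_logrank_matches_hand_computed_table(self):
        # groups A={1,2} B={3,4}, all events; O_A=2, E_A=5/6, V=17/36
        res = tx.logrank_test([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res["df"] == 1
        assert res["chi_square"] == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-6)

    def test_logrank_symmetric_in_labels(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(size=40) + 0.01
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        g = np.where(rng.random(40) < 0.5, "A", "B")
        a = tx.logrank_test(t, e, g)
        b = tx.logrank_test(t, e, np.where(g == "A", "B", "A"))
        assert a["chi_square"] == pytest.approx(b["chi_square"])

    def test_logrank_requires_events_and_two_groups(self):
        with pytest.raises(ValueError, match="no events"):
            tx.logrank_test([1.0, 2.0], [0, 0], ["A", "B"])
        with pytest.raises(ValueError, match="2 groups"):
            tx.logrank_test([1.0, 2.0], [1, 1], ["A", "A"])

    def test_logrank_null_rejection_rate_near_alpha(self):
        # identical groups: random labels on one survival distribution
        rng = np.random.default_rng(11)
        rejections = 0
        n_seeds = 500
        for _ in range(n_seeds):
            t = rng.exponential(size=60) + 1e-9
            e = np.ones(60, dtype=int)
            g = np.where(rng.random(60) < 0.5, "A", "B")
            if len(set(g)) < 2:
                continue
            rejections += tx.logrank_test(t, e, g)["p"] < 0.05
        assert abs(rejections / n_seeds - 0.05) < 0.02


class TestResponse:
    def _clin(self, responses, dialect, durations=None):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(responses))],
                "time": 1.0,
                "event": 1,
                "response": responses,
                "duration": durations if durations is not None else np.nan,
            }
        )

    def test_hugo_dialect(self):
        labels = tx.classify_response(
            self._clin(["Complete Response", "Partial Response", "Progressive Disease"], "hugo"),
            "hugo",
        )
        assert list(labels) == ["responder", "responder", "non_responder"]

    def test_riaz_excludes_stable_disease(self):
        labels = tx.classify_response(
            self._clin(["Stable Disease", "Partial Response"], "riaz"), "riaz"
        )
        assert list(labels) == ["excluded", "responder"]

    def test_jung_dialect(self):
        labels = tx.classify_response(self._clin(["DCB", "NDB"], "jung"), "jung")
        assert list(labels) == ["responder", "non_responder"]

    def test_internal_dialect_uses_stable_disease_duration(self):
        labels = tx.classify_response(
            self._clin(["SD", "SD", "PR", "PD"], "internal", [7.0, 5.0, np.nan, np.nan]),
            "internal",
        )
        assert list(labels) == ["responder", "non_responder", "responder", "non_responder"]

    def test_internal_dialect_requires_duration(self):
        with pytest.raises(ValueError, match="duration"):
            tx.classify_response(self._clin(["SD"], "internal"), "internal")

    def test_unknown_annotation_fails_loudly(self):
        with pytest.raises(ValueError, match="Mixed Response"):
            tx.classify_response(self._clin(["Mixed Response"], "hugo"), "hugo")
        with pytest.raises(ValueError, match="dialect"):
            tx.classify_response(self._clin(["PR"], "hugo"), "nonexistent")

    def test_perfect_separation_auroc_one(self):
        scores = pd.Series([-1.0, -2.0, 1.0, 2.0, 3.0])
        labels = pd.Series(["responder"] * 2 + ["non_responder"] * 3)
        res = tx.response_association(scores, labels)
        assert res["auroc"] == 1.0

    def test_all_tied_auroc_half(self):
        scores = pd.Series([1.0] * 6)
        labels = pd.Series(["responder"] * 3 + ["non_responder"] * 3)
        assert tx.response_association(scores, labels)["auroc"] == 0.5
        assert tx.response_association(scores, labels)["p"] == 1.0

    def test_excluded_samples_enter_neither_test_nor_roc(self):
        scores = pd.Series([-1.0, 0.0, 5.0])
        labels = pd.Series(["responder", "excluded", "non_responder"])
        res = tx.response_association(scores, labels)
        assert res["n_responder"] == 1 and res["n_non_responder"] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tx.response_association(
                pd.Series([1.0, 2.0]), pd.Series(["responder", "responder"])
            )

    def test_auroc_equals_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = pd.Series(rng.integers(0, 6, size=n).astype(float))
            labels = pd.Series(
                np.where(rng.random(n) < 0.5, "responder", "non_responder")
            )
            if labels.nunique() < 2:
                continue
            res = tx.response_association(scores, labels)
            r = scores[labels == "responder"].to_numpy()
            nr = scores[labels == "non_responder"].to_numpy()
            # predictor is -score: a responder pair is ordered when r < nr
            pairs = (
                (r[:, None] < nr[None, :]).sum()
                + 0.5 * (r[:, None] == nr[None, :]).sum()
            )
            assert res["auroc"] * len(r) * len(nr) == pytest.approx(pairs)
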