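"""Signature derivation, weight fusion and the score formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter

from mycnimmune.score import (
    MycnImmuneScore,
    combine_weights,
    compute_scores,
    fit_mna_logistic,
    minmax_normalize,
    penalized_cox,
    stratify,
    univariate_cox_screen,
)
from mycnimmune.simulate import CohortConfig, generate_cohort


class TestFitMnaLogistic:
    def test_planted_genes_receive_positive_weight(self, small_cohort):
        cohort, truth, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        w_pm, w_nm, aucs = fit_mna_logistic(
            expr, clin["mna_status"], n_rounds=20, seed=1)
        hit = len(set(w_pm.index) & set(truth.pos_signature)) / len(truth.pos_signature)
        assert hit >= 0.8
        assert np.mean(aucs) > 0.9

    def test_pure_noise_genes_mostly_zeroed(self, small_cohort):
        cohort, truth, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        w_pm, w_nm, _ = fit_mna_logistic(
            expr, clin["mna_status"], n_rounds=20, seed=1)
        planted = set(truth.pos_signature) | set(truth.neg_signature)
        noise = set(expr.index) - planted
        nonzero_noise = (set(w_pm.index) | set(w_nm.index)) & noise
        assert len(nonzero_noise) / len(noise) <= 0.1

    def test_seed_determinism_and_validation(self, small_cohort):
        cohort, _, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        sub = expr.iloc[:50]
        a = fit_mna_logistic(sub, clin["mna_status"], n_rounds=5, seed=3)
        b = fit_mna_logistic(sub, clin["mna_status"], n_rounds=5, seed=3)
        pd.testing.assert_series_equal(a[0], b[0])
        with pytest.raises(ValueError):
            fit_mna_logistic(sub, np.ones(expr.shape[1]), n_rounds=5)
        with pytest.raises(ValueError):
            fit_mna_logistic(sub, clin["mna_status"], n_rounds=1)


class TestUnivariateCoxScreen:
    def test_bonferroni_threshold_arithmetic(self, small_cohort):
        cohort, _, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        sub = expr.iloc[:100]
        table = univariate_cox_screen(
            sub, clin["surv_time"], clin["surv_event"], return_table=True)
        assert ((table["p"] <= 0.05 / 100) == table["pass"]).all()

    def test_matches_lifelines_on_small_data(self):
        cfg = CohortConfig(n_samples=80, n_genes=10, n_pos_genes=2,
                           n_neg_genes=2, seed=21)
        cohort, _ = generate_cohort(cfg)
        expr, clin = cohort["expression"], cohort["clinical"]
        table = univariate_cox_screen(
            expr, clin["surv_time"], clin["surv_event"], return_table=True)
        for gene in expr.index[:5]:
            x = expr.loc[gene]
            df = pd.DataFrame({
                "x": (x - x.mean()) / x.std(ddof=1),
                "t": clin["surv_time"], "e": clin["surv_event"]})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert table.loc[gene, "beta"] == pytest.approx(
                cph.summary.loc["x", "coef"], abs=1e-3)
            assert table.loc[gene, "p"] == pytest.approx(
                cph.summary.loc["x", "p"], rel=0.05, abs=1e-4)

    def test_planted_hazard_gene_selected(self):
        hits = 0
        for seed in range(5):
            cfg = CohortConfig(n_samples=500, n_genes=100, n_pos_genes=0,
                               n_neg_genes=0, censor_rate=0.06,
                               hazard_betas={"G0000": 0.8}, seed=seed)
            cohort, _ = generate_cohort(cfg)
            clin = cohort["clinical"]
            sel = univariate_cox_screen(
                cohort["expression"], clin["surv_time"], clin["surv_event"])
            hits += "G0000" in sel
        assert hits >= 4

    def test_input_validation(self, small_cohort):
        cohort, _, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        with pytest.raises(ValueError):
            univariate_cox_screen(expr, -clin["surv_time"], clin["surv_event"])
        with pytest.raises(ValueError):
            univariate_cox_screen(expr.iloc[:, :30], clin["surv_time"][:30],
                                  np.zeros(30))


class TestPenalizedCox:
    def test_sign_concordance_on_independent_plants(self):
        cfg = CohortConfig(
            n_samples=500, n_genes=40, n_pos_genes=0, n_neg_genes=0,
            hazard_betas={f"G{i:04d}": (0.6 if i < 6 else -0.6)
                          for i in range(12)},
            standardize_lp=False, hazard_pos=0, hazard_neg=0,
            baseline_hazard=0.05, censor_rate=0.03, seed=13,
        )
        cohort, truth = generate_cohort(cfg)
        clin = cohort["clinical"]
        pc, nc = penalized_cox(cohort["expression"].iloc[:12],
                               clin["surv_time"], clin["surv_event"])
        selected = list(pc.index) + list(nc.index)
        concordant = sum(
            (truth.hazard_coefficients[g] > 0) == (g in pc.index)
            for g in selected
        )
        assert concordant / len(selected) >= 0.9

    def test_zero_penalty_matches_unpenalized_cox(self):
        cfg = CohortConfig(n_samples=200, n_genes=3, n_pos_genes=0,
                           n_neg_genes=0,
                           hazard_betas={"G0000": 0.5, "G0001": -0.5},
                           standardize_lp=False, seed=17)
        cohort, _ = generate_cohort(cfg)
        expr, clin = cohort["expression"], cohort["clinical"]
        pc, nc = penalized_cox(expr, clin["surv_time"], clin["surv_event"],
                               lambda1=0.0)
        coef = pd.concat([pc, nc])
        df = expr.T.assign(t=clin["surv_time"], e=clin["surv_event"])
        cph = CoxPHFitter().fit(df, "t", "e")
        for g in coef.index:
            assert coef[g] == pytest.approx(cph.summary.loc[g, "coef"], abs=1e-3)

    def test_huge_penalty_raises(self, small_cohort):
        cohort, _, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        with pytest.raises(ValueError, match="smaller lambda1"):
            penalized_cox(expr.iloc[:20], clin["surv_time"],
                          clin["surv_event"], lambda1=1e6)


class TestWeightAlgebra:
    def test_minmax_printed_examples(self):
        np.testing.assert_allclose(
            minmax_normalize(pd.Series([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0])
        np.testing.assert_allclose(
            minmax_normalize(pd.Series([-3.0, -1.0])), [0.0, 1.0])
        with pytest.raises(ValueError):
            minmax_normalize(pd.Series([1.0, 1.0]))

    def test_minmax_negate_orients_strongest_protective_to_one(self):
        w = pd.Series({"A": -3.0, "B": -1.0})
        out = minmax_normalize(w, negate=True)
        assert out["A"] == 1.0 and out["B"] == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_minmax_bounds_property(self, values):
        out = minmax_normalize(pd.Series(values))
        assert out.min() == 0.0 and out.max() == 1.0
        assert ((out >= 0) & (out <= 1)).all()

    def test_combine_weights_rules(self):
        pm = pd.Series({"A": 0.4, "B": 0.9})
        pc = pd.Series({"A": 0.3, "C": 0.6})
        nm = pd.Series({"D": 0.2})
        nc = pd.Series({"D": 0.7, "E": 0.1})
        pos, neg = combine_weights(pm, pc, nm, nc)
        assert pos.to_dict() == pytest.approx({"A": 0.7})
        assert "B" not in pos.index and "C" not in pos.index
        assert neg.to_dict() == pytest.approx({"D": 0.9})
        assert ((pos >= 0) & (pos <= 2)).all()
        with pytest.raises(ValueError):
            combine_weights(pm, pd.Series({"Z": 0.1}), nm, nc)


class TestComputeScores:
    def _toy(self):
        expr = pd.DataFrame({"P1": [2.0, 4.0, 1.0, 1.0],
                             "P2": [1.0, 1.0, 3.0, 2.0]},
                            index=["g1", "g2", "g3", "g4"])
        pos = pd.Series({"g1": 1.0, "g2": 0.5})
        neg = pd.Series({"g3": 1.0, "g4": 1.0})
        return expr, pos, neg

    def test_hand_arithmetic_oracle(self):
        expr, pos, neg = self._toy()
        out = compute_scores(expr, pos, neg)
        assert out.loc["P1", "immP"] == pytest.approx((2 * 1.0 + 4 * 0.5) / 2)
        assert out.loc["P1", "immN"] == pytest.approx((1.0 + 1.0) / 2)
        assert out.loc["P1", "score"] == pytest.approx(2.0 / 1.0)

    def test_identical_signatures_score_one(self):
        expr, pos, _ = self._toy()
        out = compute_scores(expr, pos, pos)
        np.testing.assert_allclose(out["score"], 1.0)

    def test_ratio_invariant_to_doubling(self):
        expr, pos, neg = self._toy()
        a = compute_scores(expr, pos, neg)
        b = compute_scores(expr * 2, pos, neg)
        np.testing.assert_allclose(a["score"], b["score"])
        np.testing.assert_allclose(2 * a["immP"], b["immP"])

    def test_sample_order_and_outside_genes_irrelevant(self, rng):
        expr, pos, neg = self._toy()
        extra = expr.copy()
        extra.loc["zzz"] = rng.normal(size=2)
        a = compute_scores(expr, pos, neg)
        b = compute_scores(extra[["P2", "P1"]], pos, neg)
        np.testing.assert_allclose(a.loc[["P1", "P2"], "score"],
                                   b.loc[["P1", "P2"], "score"])

    def test_scale_and_coverage_errors(self):
        expr, pos, neg = self._toy()
        with pytest.raises(ValueError, match="non-positive immN"):
            compute_scores(expr - 5.0, pos, neg)
        with pytest.raises(ValueError, match="signature genes present"):
            compute_scores(expr.drop(index=["g3"]), pos, neg)


class TestStratify:
    @pytest.mark.parametrize(
        "z,expected",
        [(-0.6, "low"), (0.0, "medium"), (1.2, "high"),
         (-0.5, "medium"), (1.0, "medium")],
    )
    def test_boundaries(self, z, expected):
        assert stratify([z]).iloc[0] == expected

    @given(st.lists(st.floats(-4, 4), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_strata_partition_cohort(self, zs):
        out = stratify(zs)
        assert len(out) == len(zs)
        assert set(out) <= {"low", "medium", "high"}


class TestEstimator:
    def test_end_to_end_fit_transform(self, small_cohort):
        cohort, truth, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        model = MycnImmuneScore(n_rounds=15, random_state=0)
        scores = model.fit_transform(
            expr, clin["mna_status"], clin["surv_time"], clin["surv_event"])
        assert set(scores.columns) == {"immP", "immN", "score", "z", "stratum"}
        assert len(scores) == expr.shape[1]
        planted = set(truth.pos_signature) | set(truth.neg_signature)
        sig = set(model.positive_signature_.index) | set(
            model.negative_signature_.index)
        assert sig and sig <= planted
        assert model.get_params()["lambda1"] == 0.25

    def test_immune_gene_restriction(self, small_cohort):
        cohort, truth, _ = small_cohort
        expr, clin = cohort["expression"], cohort["clinical"]
        immune = list(truth.pos_signature) + list(truth.neg_signature)
        model = MycnImmuneScore(n_rounds=10, random_state=0)
        model.fit(expr, clin["mna_status"], clin["surv_time"],
                  clin["surv_event"], immune_genes=immune)
        assert set(model.positive_signature_.index) <= set(immune)
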