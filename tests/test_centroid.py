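"""Centroid classifier: scoring contracts, calibration, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from chemosig import (
    CentroidClassifier,
    CentroidModel,
    SimulationConfig,
    evaluate,
    fit_centroid_model,
    predict,
    simulate_bulk_cohort,
)
from chemosig.exceptions import EvaluationError, InputError, ModelError

from conftest import make_phenotype


def _toy_cohort():
    """4 genes x 8 samples with two perfectly separating genes."""
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(
        rng.normal(0, 0.1, (4, 8)), index=["gA", "gB", "gC", "gD"], columns=[f"s{i}" for i in range(8)]
    )
    expr.loc["gA", ["s4", "s5", "s6", "s7"]] += 3.0
    expr.loc["gB", ["s4", "s5", "s6", "s7"]] += 3.0
    pheno = make_phenotype(expr.columns, ["R"] * 4 + ["NR"] * 4)
    return expr, pheno


class TestFit:
    def test_sample_at_nr_centroid_called_nr(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        est = model.estimator
        # a synthetic sample sitting exactly on the NR centroid
        nr_profile = est.gene_mean_ + est.gene_sd_ * est.centroid_pos_
        probe = pd.DataFrame({"probe": nr_profile}, index=est.panel_genes_)
        out = predict(model, probe)
        assert out.loc["probe", "call"] == "NR"
        assert out.loc["probe", "score_z"] >= est.threshold_

    def test_perfect_separators_train_auc_one(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        assert evaluate(model, expr, pheno).auc == 1.0

    def test_label_swap_negates_scores(self):
        expr, pheno = _toy_cohort()
        swapped = pheno.copy()
        swapped["response"] = np.where(pheno["response"] == "R", "NR", "R")
        m1 = fit_centroid_model(expr, pheno, list(expr.index))
        m2 = fit_centroid_model(expr, swapped, list(expr.index))
        z1 = predict(m1, expr)["score_z"]
        z2 = predict(m2, expr)["score_z"]
        np.testing.assert_allclose(z1.to_numpy(), -z2.to_numpy(), atol=1e-10)

    def test_zero_variance_gene_dropped(self):
        expr, pheno = _toy_cohort()
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_centroid_model(expr, pheno, list(expr.index))
        assert "flat" not in model.genes

    def test_too_few_genes_rejected(self):
        expr, pheno = _toy_cohort()
        with pytest.raises(ModelError):
            fit_centroid_model(expr, pheno, ["gA", "gB"])

    def test_small_class_rejected(self):
        expr, pheno = _toy_cohort()
        bad = make_phenotype(expr.columns, ["R"] * 7 + ["NR"])
        with pytest.raises(InputError):
            fit_centroid_model(expr, bad, list(expr.index))


class TestPredict:
    def test_probability_monotone_in_score(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        out = predict(model, expr).sort_values("score_z")
        assert out["prob_nonresponse"].is_monotonic_increasing

    def test_probability_half_at_threshold(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        est = model.estimator
        p_at_thr = 1.0 / (1.0 + np.exp(-(est.calib_intercept_ + est.calib_slope_ * est.threshold_)))
        assert p_at_thr == pytest.approx(0.5, abs=1e-9)

    def test_train_statistics_frozen_for_prediction(self):
        """Scores on test data use training scaling only: scoring the
        training matrix through predict() reproduces the fit-time scores."""
        cfg = SimulationConfig(n_genes=30, n_samples_R=15, n_samples_NR=15, n_signal_genes=10, seed=2)
        cohort = simulate_bulk_cohort(cfg)
        model = fit_centroid_model(cohort.expression, cohort.phenotype, cohort.truth)
        z_again = predict(model, cohort.expression)["score_z"].to_numpy()
        est = model.estimator
        z_direct = est.decision_function(cohort.expression.T)
        np.testing.assert_allclose(z_again, z_direct, atol=1e-12)
        assert z_again.mean() == pytest.approx(0.0, abs=1e-9)  # z-standardized on train

    def test_validation_auc_on_fresh_cohort(self):
        """20-gene panel at delta=1.5: held-out AUC clears the
        analytic multi-gene bound Phi(delta*sqrt(g)/sqrt(2)) ~ 1."""
        cfg = SimulationConfig(n_genes=60, n_samples_R=50, n_samples_NR=50, n_signal_genes=20,
                               effect_size_delta=1.5, seed=3)
        train = simulate_bulk_cohort(cfg)
        model = fit_centroid_model(train.expression, train.phenotype, train.truth)
        fresh = simulate_bulk_cohort(
            SimulationConfig(n_genes=60, n_samples_R=50, n_samples_NR=50, n_signal_genes=20,
                             effect_size_delta=1.5, seed=303)
        )
        assert evaluate(model, fresh.expression, fresh.phenotype).auc >= 0.9

    def test_missing_panel_genes(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        with pytest.warns(UserWarning, match="missing"):
            out = predict(model, expr.drop(index="gD"))
        assert len(out) == expr.shape[1]
        with pytest.raises(ModelError):
            predict(model, expr.drop(index=["gB", "gC", "gD"]))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        path = tmp_path / "model.json"
        model.to_json(path)
        reloaded = CentroidModel.from_json(path)
        pd.testing.assert_frame_equal(predict(model, expr), predict(reloaded, expr))


class TestEvaluate:
    def test_perfect_separation_significant(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        roc = evaluate(model, expr, pheno)
        assert roc.auc == 1.0 and roc.p_value < 0.05

    def test_null_cohort_auc_near_half(self, null_cohort):
        panel = list(null_cohort.expression.index[:10])
        model = fit_centroid_model(null_cohort.expression, null_cohort.phenotype, panel)
        fresh = simulate_bulk_cohort(
            SimulationConfig(n_genes=50, n_samples_R=100, n_samples_NR=100, n_signal_genes=0, seed=24)
        )
        roc = evaluate(model, fresh.expression, fresh.phenotype)
        assert 0.4 <= roc.auc <= 0.6

    def test_sample_order_invariance(self, strong_cohort):
        expr, pheno = strong_cohort.expression, strong_cohort.phenotype
        model = fit_centroid_model(expr, pheno, strong_cohort.truth)
        perm = list(np.random.default_rng(1).permutation(expr.columns))
        a = evaluate(model, expr, pheno)
        b = evaluate(model, expr[perm], pheno.loc[perm])
        assert a.auc == b.auc and a.p_value == pytest.approx(b.p_value)

    def test_single_class_rejected(self):
        expr, pheno = _toy_cohort()
        model = fit_centroid_model(expr, pheno, list(expr.index))
        only_r = make_phenotype(expr.columns, ["R"] * 8)
        with pytest.raises(EvaluationError):
            evaluate(model, expr, only_r)

    def test_resolution_property(self, strong_cohort):
        """Mean predicted nonresponse probability is higher among NR."""
        expr, pheno = strong_cohort.expression, strong_cohort.phenotype
        model = fit_centroid_model(expr, pheno, strong_cohort.truth)
        out = predict(model, expr)
        probs = out["prob_nonresponse"].groupby(pheno["response"]).mean()
        assert probs["NR"] > probs["R"]


class TestSklearnSurface:
    def test_params_round_trip_and_clone(self):
        est = CentroidClassifier(panel=["a", "b", "c"], distance="correlation")
        cloned = clone(est)
        assert cloned.get_params()["panel"] == ["a", "b", "c"]
        assert cloned.get_params()["distance"] == "correlation"

    def test_array_input_and_predict_labels(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (40, 6))
        y = np.array(["R"] * 20 + ["NR"] * 20)
        X[y == "NR", :3] += 2.0
        est = CentroidClassifier().fit(X, y)
        preds = est.predict(X)
        assert set(preds) <= {"R", "NR"}
        assert (preds == y).mean() > 0.9
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_correlation_mode_contracts_hold(self):
        # both distance modes satisfy the orientation/antisymmetry contract
        expr, pheno = _toy_cohort()
        m = fit_centroid_model(expr, pheno, list(expr.index), distance="correlation")
        swapped = pheno.copy()
        swapped["response"] = np.where(pheno["response"] == "R", "NR", "R")
        m2 = fit_centroid_model(expr, swapped, list(expr.index), distance="correlation")
        np.testing.assert_allclose(
            predict(m, expr)["score_z"].to_numpy(), -predict(m2, expr)["score_z"].to_numpy(), atol=1e-10
        )

    def test_welch_p_matches_hand_formula(self, strong_cohort):
        expr, pheno = strong_cohort.expression, strong_cohort.phenotype
        model = fit_centroid_model(expr, pheno, strong_cohort.truth)
        roc = evaluate(model, expr, pheno)
        z = predict(model, expr)["score_z"]
        pos = z[pheno["response"] == "NR"].to_numpy()
        neg = z[pheno["response"] == "R"].to_numpy()
        expected = sps.ttest_ind(pos, neg, equal_var=False).pvalue
        assert roc.p_value == pytest.approx(expected, rel=1e-9)
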