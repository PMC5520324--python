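import numpy as np
import pandas as pd
import pytest

import painfusion as pf
from painfusion.arx import (ARXSpec, PainARXModel, build_design,
                            cross_correlation_screen, predict_trajectory,
                            roc_responder, stepwise_select)
from painfusion.equations import CLUSTER_EQUATIONS
from painfusion.errors import (PredictionError, SingularFitError,
                               SpecificationError)

from _oracles import normal_equations_ols
from conftest import single_cluster_cohort


def spec_for(cluster):
    return ARXSpec(tuple(t for t in CLUSTER_EQUATIONS[cluster]
                         if t != "const"))


def one_patient_panel(weeks, pain=None):
    rows = []
    for i, w in enumerate(weeks):
        rows.append({"patient_id": "P1", "week": w,
                     "pain": 5.0 + 0.1 * i if pain is None else pain[i],
                     "sleep": 4.0 + 0.1 * i, "dose_mg": 150.0,
                     "feeling_energy": 3, "feeling_calm": 3,
                     "feeling_discouraged": 3, "observed": True})
    return pd.DataFrame(rows)


ONE_COHORT = pd.DataFrame([{
    "patient_id": "P1", "insulin": 0, "monotherapy": 1, "gender_code": 0,
    "age_cohort_code": 1, "pdpn_duration": 5.0, "baseline_pain": 5.0}])


class TestBuildDesign:
    def test_lag2_spec_gives_five_rows(self):
        panel = one_patient_panel(range(7))
        d = build_design(panel, ONE_COHORT, spec_for(1))
        assert len(d) == 5
        assert list(d.index.get_level_values("week")) == [2, 3, 4, 5, 6]

    def test_lag1_only_spec_gives_six_rows(self):
        panel = one_patient_panel(range(7))
        spec = ARXSpec(("x1", "x3"))
        d = build_design(panel, ONE_COHORT, spec)
        assert len(d) == 6

    def test_missing_final_week_drops_final_row(self):
        panel = one_patient_panel(range(7))
        panel.loc[panel["week"] == 6, "pain"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            d = build_design(panel, ONE_COHORT, spec_for(1))
        assert list(d.index.get_level_values("week")) == [2, 3, 4, 5]

    def test_unknown_term_rejected(self):
        with pytest.raises(SpecificationError):
            ARXSpec(("x1", "x99"))


class TestFit:
    def test_matches_normal_equations_oracle(self):
        panel = pd.concat([one_patient_panel(range(7))])
        rng = np.random.default_rng(0)
        cohort, panel = single_cluster_cohort(1, 60, seed=13, noise_sd=0.5)
        res = PainARXModel.from_panel(panel, cohort, spec_for(1)).fit()
        model = PainARXModel.from_panel(panel, cohort, spec_for(1))
        X = np.column_stack([np.ones(len(model.endog)), model.exog])
        beta = normal_equations_ols(X, model.endog)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_intercept_only_returns_mean(self):
        cohort, panel = single_cluster_cohort(1, 30, seed=2, noise_sd=0.3)
        res = PainARXModel.from_panel(panel, cohort, ARXSpec(())).fit()
        d = build_design(panel, cohort, ARXSpec(()))
        assert res.params["const"] == pytest.approx(d["y"].mean())

    @pytest.mark.parametrize("cluster", range(1, 7))
    def test_noiseless_roundtrip_recovers_equations(self, cluster):
        """Zero-noise simulation from each reference equation refits to the
        printed coefficients to better than 1e-6."""
        cohort, panel = single_cluster_cohort(cluster, 150, seed=cluster,
                                              noise_sd=0.0)
        eq = CLUSTER_EQUATIONS[cluster]
        res = PainARXModel.from_panel(panel, cohort,
                                      spec_for(cluster)).fit()
        for term, beta in eq.items():
            assert res.params[term] == pytest.approx(beta, abs=1e-7)
        assert res.rmse < 1e-8
        assert res.rsquared > 1 - 1e-12

    def test_singular_design_names_terms(self):
        cohort, panel = single_cluster_cohort(1, 40, seed=3, noise_sd=0.0,
                                              )
        # duplicate dose columns: x5 == x6 when dose is constant in time
        panel = panel.copy()
        panel["dose_mg"] = 300.0
        with pytest.raises(SingularFitError, match="x"):
            PainARXModel.from_panel(panel, cohort, ARXSpec(("x1", "x5",
                                                            "x6"))).fit()

    def test_consistency_with_sample_size(self):
        """Estimates tighten as the cohort grows (SE ~ 1/sqrt(n))."""
        eq = CLUSTER_EQUATIONS[1]
        out = {}
        for n in (200, 2000):
            cohort, panel = single_cluster_cohort(1, n, seed=17,
                                                  noise_sd=0.54)
            res = PainARXModel.from_panel(panel, cohort, spec_for(1)).fit()
            out[n] = res
            assert abs(res.params["x1"] - eq["x1"]) < 3 * res.bse["x1"]
        ratio = out[200].bse["x1"] / out[2000].bse["x1"]
        assert 2.0 < ratio < 5.0

    def test_loglik_beats_intercept_only(self):
        cohort, panel = single_cluster_cohort(1, 100, seed=19, noise_sd=0.54)
        full = PainARXModel.from_panel(panel, cohort, spec_for(1)).fit()
        null = PainARXModel.from_panel(panel, cohort, ARXSpec(())).fit()
        assert full.llf >= null.llf
        assert full.lr_pvalue < 1e-10

    def test_summary_renders(self):
        cohort, panel = single_cluster_cohort(1, 60, seed=23, noise_sd=0.5)
        res = PainARXModel.from_panel(panel, cohort, spec_for(1)).fit()
        text = str(res.summary())
        assert "x1" in text and "x11" in text


class TestStepwise:
    def test_recovers_generating_support(self):
        """Selection keeps every generating term and rejects most noise
        candidates on a large synthetic cluster."""
        cohort, panel = single_cluster_cohort(1, 800, seed=29, noise_sd=0.54)
        truth = set(CLUSTER_EQUATIONS[1]) - {"const"}
        candidates = ARXSpec(tuple(sorted(truth | {"x7", "x8", "x9", "x10"},
                                          key=lambda t: int(t[1:]))))
        model = PainARXModel.from_panel(panel, cohort, candidates)
        res = stepwise_select(model, alpha=0.05)
        selected = set(res.model.spec.terms)
        assert truth <= selected
        assert len(selected - truth) <= 1

    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(31)
        n = 400
        design = pd.DataFrame({
            "y": rng.normal(size=n),
            "x7": rng.normal(size=n), "x8": rng.normal(size=n),
            "x9": rng.normal(size=n), "x10": rng.normal(size=n)})
        with pytest.warns(UserWarning, match="intercept-only"):
            res = stepwise_select(PainARXModel(design), alpha=0.05)
        assert res.model.spec.terms == ()


class TestPredictTrajectory:
    def test_constant_intercept_model(self):
        panel = one_patient_panel(range(7))
        pred = predict_trajectory({"const": 5.0}, ONE_COHORT.iloc[0], panel)
        assert (pred == 5.0).all()

    def test_cluster2_hand_evaluation(self):
        """Frozen hand sum of the cluster-2 equation with pain lags 6,
        dose 150 at all lags and energy 3."""
        val = pf.linear_predictor(CLUSTER_EQUATIONS[2],
                                  {"x1": 6, "x2": 6, "x4": 150, "x5": 150,
                                   "x6": 150, "x13": 3})
        assert val == pytest.approx(5.3273)

    def test_week1_uses_zero_dose_before_baseline(self):
        """At the first step the lag-2 dose reaches below week 0 and is 0
        by the baseline-carry convention."""
        panel = one_patient_panel(range(7), pain=[6] * 7)
        patient = pd.Series({"baseline_pain": 6.0})
        pred = predict_trajectory(CLUSTER_EQUATIONS[2], patient, panel,
                                  weeks=[1])
        expected = pf.linear_predictor(
            CLUSTER_EQUATIONS[2], {"x1": 6, "x2": 6, "x4": 150, "x5": 150,
                                   "x6": 0, "x13": 3})
        assert pred.loc[1] == pytest.approx(expected)

    def test_noiseless_patient_predicted_exactly(self):
        cohort, panel = single_cluster_cohort(3, 20, seed=37, noise_sd=0.0)
        eq = CLUSTER_EQUATIONS[3]
        pid = cohort["patient_id"].iloc[0]
        patient = cohort.set_index("patient_id").loc[pid]
        grp = panel[panel["patient_id"] == pid]
        pred = predict_trajectory(eq, patient, grp, dynamic=True)
        obs = grp.set_index("week")["pain"]
        np.testing.assert_allclose(pred.to_numpy(),
                                   obs.loc[pred.index].to_numpy(), atol=1e-10)

    def test_missing_exogenous_reported(self):
        panel = one_patient_panel(range(7))
        with pytest.raises(PredictionError, match="pdpn_duration"):
            predict_trajectory(CLUSTER_EQUATIONS[1],
                               pd.Series({"baseline_pain": 5.0}), panel)


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, complete_cohort):
        _, panel = complete_cohort
        corr = cross_correlation_screen(panel, candidates=("pain",))
        assert corr.loc["pain", 0] == pytest.approx(1.0)

    def test_generated_sleep_pain_coupling_reported(self, complete_cohort):
        """The generator couples sleep to pain strongly enough to clear the
        0.70 reporting threshold at lag 0."""
        from painfusion.arx import format_correlation_report
        _, panel = complete_cohort
        corr = cross_correlation_screen(panel, candidates=("sleep",))
        assert corr.loc["sleep", 0] >= 0.70
        rep = format_correlation_report(corr)
        assert rep.loc["sleep", 0] == corr.loc["sleep", 0]

    def test_independent_noise_near_zero(self, complete_cohort):
        _, panel = complete_cohort
        panel = panel.copy()
        rng = np.random.default_rng(41)
        panel["noise_var"] = rng.normal(size=len(panel))
        corr = cross_correlation_screen(panel, candidates=("noise_var",))
        assert abs(corr.loc["noise_var", 0]) < 0.1

    def test_constant_series_undefined(self, complete_cohort):
        _, panel = complete_cohort
        panel = panel.copy()
        panel["flat"] = 1.0
        corr = cross_correlation_screen(panel, candidates=("flat",))
        assert np.isnan(corr.loc["flat", 0])


class TestROC:
    def test_perfect_predictions(self):
        lv = np.array([0.1, 0.2, 0.6, 0.9, 0.4, 0.55])
        roc = roc_responder(lv, lv)
        assert roc["auc"] == pytest.approx(1.0)

    def test_independent_predictions_near_half(self):
        rng = np.random.default_rng(43)
        obs = rng.uniform(0, 1, size=4000)
        pred = rng.uniform(0, 1, size=4000)
        roc = roc_responder(obs, pred)
        assert roc["auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_undefined(self):
        roc = roc_responder([0.9, 0.8, 0.95], [0.5, 0.6, 0.7])
        assert roc["auc"] is None

    def test_noisy_cluster_auc_between_half_and_one(self):
        cohort, panel = single_cluster_cohort(1, 120, seed=47, noise_sd=0.54)
        eq = CLUSTER_EQUATIONS[1]
        cov = cohort.set_index("patient_id")
        obs_lv, pred_lv = [], []
        for pid, grp in panel.groupby("patient_id"):
            g = grp.set_index("week")
            pred = predict_trajectory(eq, cov.loc[pid], grp, dynamic=True)
            base = g.loc[0, "pain"]
            if base <= 0:
                continue
            obs_lv.append(pf.responder_level(base, g.loc[6, "pain"]))
            pred_lv.append(pf.responder_level(base, pred.loc[6]))
        roc = roc_responder(np.array(obs_lv), np.array(pred_lv))
        assert 0.5 < roc["auc"] < 1.0
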