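"""Person-period expansion, likelihood maximization, survival prediction."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import pktsurv as pk
from pktsurv.hazard import (DONOR_FIELDS, FitError, ModelSpec, SeparationError,
                            _build_design, _design_columns)

from conftest import (DUMMY_SPEC, grid_search_logistic, make_cohort_df,
                      toy_person_period)


class TestExpandPersonPeriod:
    def test_event_only_in_final_month_of_graft_loss(self):
        df = make_cohort_df(1, follow_up_months=3, graft_loss=1)
        pp = pk.expand_person_period(pk.CohortTable(df=df), DUMMY_SPEC)
        assert pp.df["month"].tolist() == [1, 2, 3]
        assert pp.df["event"].tolist() == [0, 0, 1]

    def test_censored_subject_has_no_event_rows(self):
        df = make_cohort_df(1, follow_up_months=5, graft_loss=0, death_with_function=1)
        pp = pk.expand_person_period(pk.CohortTable(df=df), DUMMY_SPEC)
        assert len(pp) == 5
        assert pp.df["event"].sum() == 0

    def test_row_conservation(self):
        df = make_cohort_df(3, follow_up_months=[3, 5, 12], graft_loss=[1, 0, 1])
        pp = pk.expand_person_period(pk.CohortTable(df=df), DUMMY_SPEC)
        assert len(pp) == 20
        assert pp.n_events == 2
        assert pp.df.groupby("subject_id")["month"].apply(
            lambda m: (m.to_numpy() == np.arange(1, len(m) + 1)).all()).all()

    def test_spline_columns_attached(self, default_registry):
        filt, _ = pk.apply_inclusion(default_registry)
        pp = pk.expand_person_period(filt)
        assert {f"t{j}" for j in range(1, 6)} <= set(pp.df.columns)
        assert len(pp) == filt.df["follow_up_months"].sum()
        assert pp.n_events == filt.df["graft_loss"].sum()


REDUCED = ModelSpec(covariates=("x1",), include_disease=False, include_time=False)


class TestFitHazard:
    def test_intercept_only_closed_form(self):
        # with no covariates the MLE of the intercept is logit of event rate
        rows = [(1, 0)] * 7 + [(0, 0)] * 33
        pp = toy_person_period(rows)
        model = pk.fit_hazard(pp, ModelSpec(covariates=(), include_disease=False,
                                            include_time=False))
        assert model.intercept == pytest.approx(logit(7 / 40), abs=1e-6)

    def test_matches_grid_search_oracle_single_covariate(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 40)
        y = (rng.random(40) < expit(-1.0 + 1.2 * x)).astype(int)
        if y.sum() == 0:
            y[0] = 1
        pp = toy_person_period(list(zip(y, x)))
        model = pk.fit_hazard(pp, REDUCED)
        X = np.column_stack([np.ones(40), x])
        oracle = grid_search_logistic(X, y)
        assert model.intercept == pytest.approx(oracle[0], abs=2e-3)
        assert model.coef["x1"] == pytest.approx(oracle[1], abs=2e-3)

    def test_matches_statsmodels_glm_on_expanded_data(self, default_registry):
        """Independent cross-check of the Newton fit against a reference GLM."""
        import statsmodels.api as sm
        filt, _ = pk.apply_inclusion(default_registry)
        pp = pk.expand_person_period(filt)
        spec = ModelSpec()
        model = pk.fit_hazard(pp, spec)
        basis = pp.df[[f"t{j}" for j in range(1, 6)]].to_numpy()
        X = _build_design(pp.df, spec, basis)
        res = sm.GLM(pp.df["event"].to_numpy(), X,
                     family=sm.families.Binomial()).fit(maxiter=200, tol=1e-12)
        names = _design_columns(spec) + [f"t{j}" for j in range(1, 6)]
        mine = np.array([model.coef[c] for c in names])
        assert np.allclose(mine, res.params, atol=1e-5)
        assert model.log_likelihood == pytest.approx(res.llf, abs=1e-6)

    def test_no_events_is_an_error(self):
        pp = toy_person_period([(0, 1)] * 12)
        with pytest.raises(FitError):
            pk.fit_hazard(pp, REDUCED)

    def test_separation_raises_unless_penalized(self):
        rows = [(1, 1)] * 10 + [(0, 0)] * 10  # x perfectly predicts y
        pp = toy_person_period(rows)
        with pytest.raises(SeparationError):
            pk.fit_hazard(pp, REDUCED)
        from dataclasses import replace
        model = pk.fit_hazard(pp, replace(REDUCED, penalty=1e-6))
        assert model.coef["x1"] > 0

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 60)
        y = (rng.random(60) < expit(-1.5 + x)).astype(int)
        y[0] = 1
        pp1 = toy_person_period(list(zip(y, x)))
        pp2 = toy_person_period(list(zip(y, x)))
        pp2.df["weight"] = np.ones(60)
        m1, m2 = pk.fit_hazard(pp1, REDUCED), pk.fit_hazard(pp2, REDUCED)
        for k in m1.coef:
            assert m1.coef[k] == pytest.approx(m2.coef[k], abs=1e-10)

    def test_parameter_recovery_small(self, default_registry):
        """Moderate-n sanity recovery; the full multi-seed version is an
        acceptance-level check."""
        truth = pk.default_truth()
        profiles = pk.default_profiles()
        table = pk.generate_registry(profiles, truth, seed=77)
        filt, _ = pk.apply_inclusion(table)
        pp = pk.expand_person_period(filt)
        model = pk.fit_hazard(pp)
        assert model.converged
        for name, tol in [("living_donor", 0.25), ("retransplant", 0.35)]:
            assert model.coef[name] == pytest.approx(truth.beta[name], abs=tol)


@pytest.fixture
def zero_model():
    rows = [(1, 0), (0, 0), (1, 1), (0, 1)] * 5
    pp = toy_person_period(rows)
    model = pk.fit_hazard(pp, REDUCED)
    model.coef = {k: 0.0 for k in model.coef}
    return model


class TestPrediction:
    def test_all_zero_coefficients_give_half(self, zero_model):
        rec = {"x1": 1.0}
        assert pk.predict_hazard(zero_model, rec, 1) == pytest.approx(0.5)
        assert pk.predict_hazard(zero_model, rec, 37) == pytest.approx(0.5)

    def test_hazard_monotone_in_covariate(self, fitted_model):
        model, _, _ = fitted_model
        base = make_cohort_df(1).iloc[0]
        sign = np.sign(model.coef["hla_mm"])
        h = [pk.predict_hazard(model, base.to_dict() | {"hla_mm": v}, 12)
             for v in (0, 3, 6)]
        diffs = np.diff(h) * sign
        assert (diffs > 0).all()

    def test_hand_computed_inverse_logit(self, zero_model):
        model = zero_model
        model.coef = dict(model.coef)
        model.coef["(intercept)"] = -2.0
        model.coef["x1"] = 0.5
        # lp = -2 + 0.5*3 = -0.5 (no time effect in the reduced model)
        assert pk.predict_hazard(model, {"x1": 3.0}, 5) == pytest.approx(expit(-0.5), abs=1e-12)

    def test_constant_hazard_survival_closed_form(self, zero_model):
        curve = pk.predict_survival(zero_model, {"x1": 0.0}, horizon=12)
        assert curve.survival[-1] == pytest.approx(0.5**12, rel=1e-12)

    def test_vanishing_hazard_gives_unit_survival(self, zero_model):
        model = zero_model
        model.coef = dict(model.coef)
        model.coef["(intercept)"] = -40.0
        curve = pk.predict_survival(model, {"x1": 0.0}, horizon=120)
        assert np.all(curve.survival > 1 - 1e-10)

    def test_survival_identity_and_monotonicity(self, fitted_model):
        model, _, fr = fitted_model
        curve = pk.predict_survival(model, fr.df.iloc[0], horizon=180)
        S, h = curve.survival, curve.hazard
        assert np.all(np.diff(S) <= 0)
        assert np.allclose(S[:-1] * (1 - h[1:]), S[1:], atol=1e-12)
        assert S[0] == pytest.approx(1 - h[0], abs=1e-12)

    def test_mean_predicted_curve_matches_truth(self):
        """Fitting data simulated from a known hazard reproduces the truth
        survival within 0.01 at years 1, 5, 10 on the simulated mix."""
        truth = pk.default_truth(admin_horizon=120, study_end_year=None)
        table = pk.generate_registry(pk.default_profiles(), truth, seed=15)
        filt, _ = pk.apply_inclusion(table)
        pp = pk.expand_person_period(filt)
        model = pk.fit_hazard(pp)
        S_fit = pk.predict_survival_matrix(model, filt.df, 120).mean(axis=0)
        S_true = truth.survival_curve(filt.df, 120).mean(axis=0)
        for month in (12, 60, 120):
            assert abs(S_fit[month - 1] - S_true[month - 1]) <= 0.01


class TestScenarios:
    def test_identical_variants_identical_curves(self, fitted_model):
        model, _, fr = fitted_model
        rec = fr.df.iloc[4]
        a, b = pk.compare_scenarios(model, rec, [{"donor_age": 30}, {"donor_age": 30}], 60)
        assert np.array_equal(a.survival, b.survival)

    def test_composition_matches_predict_survival(self, fitted_model):
        model, _, fr = fitted_model
        rec = fr.df.iloc[4]
        variants = [{"donor_age": 20.0, "living_donor": 1}, {"hla_mm": 6}]
        curves = pk.compare_scenarios(model, rec, variants, 60)
        for v, c in zip(variants, curves):
            direct = pk.predict_survival(model, rec.to_dict() | v, 60)
            assert np.array_equal(c.survival, direct.survival)

    def test_worse_donor_lowers_survival_pointwise(self, fitted_model):
        model, _, fr = fitted_model
        rec = fr.df.iloc[4].to_dict() | {"hla_mm": 1}
        sign = np.sign(model.coef["hla_mm"])
        lo, hi = (1, 6) if sign > 0 else (6, 1)
        good, bad = pk.compare_scenarios(model, rec, [{"hla_mm": lo}, {"hla_mm": hi}], 120)
        assert np.all(bad.survival < good.survival)

    def test_recipient_side_override_rejected(self, fitted_model):
        model, _, fr = fitted_model
        with pytest.raises(ValueError, match="donor-side"):
            pk.compare_scenarios(model, fr.df.iloc[0], [{"recipient_age": 5}], 12)


class TestSerialization:
    def test_json_round_trip_bit_stable(self, fitted_model, tmp_path):
        model, _, _ = fitted_model
        s1 = model.to_json()
        back = pk.FittedHazardModel.from_json(s1)
        assert back.to_json() == s1
        assert np.array_equal(back.gamma, model.gamma)
        assert back.spline_spec == model.spline_spec
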