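"""Harmonic mixed model: design, fitting, stepwise selection, amplitudes."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cardioday.circadian_model import (
    FULL_TERMS,
    HARMONICS,
    amplitude_summary,
    backward_stepwise,
    build_design,
    covariate_check,
    fit_lmm,
    harmonic_columns,
    predict_curve,
)
from cardioday.synthetic_data import DEFAULT_LOGHR_COEFS, simulate_hourly_cohort


@pytest.fixture(scope="module")
def design():
    return build_design(simulate_hourly_cohort(seed=7))


@pytest.fixture(scope="module")
def reml_fit(design):
    return fit_lmm(design, "log_hr")


class TestHarmonicDesign:
    @pytest.mark.parametrize(
        "t,expected",
        [(0, (0, 1, 0, 1)), (6, (1, 0, 0, -1)), (12, (0, -1, 0, 1)), (18, (-1, 0, 0, -1))],
    )
    def test_cardinal_hours(self, t, expected):
        hc = harmonic_columns([t]).iloc[0]
        np.testing.assert_allclose(hc[["s24", "c24", "s12", "c12"]], expected, atol=1e-12)

    def test_unit_circle_identity(self):
        hc = harmonic_columns(np.linspace(0, 24, 97))
        np.testing.assert_allclose(hc["s24"] ** 2 + hc["c24"] ** 2, 1.0)
        np.testing.assert_allclose(hc["s12"] ** 2 + hc["c12"] ** 2, 1.0)

    def test_orthogonality_on_balanced_grid(self):
        hc = harmonic_columns(np.arange(24))
        gram = hc.to_numpy().T @ hc.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10


class TestBuildDesign:
    def test_group_and_sex_coding(self):
        records = pd.DataFrame(
            {"subject_id": ["a", "b"], "clock_hour": [0, 0], "log_hr": [4.0, 4.2]}
        )
        meta = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "group": ["control", "patient"],
                "age": [40.0, 50.0],
                "sex": ["female", "male"],
                "bmi": [24.0, 30.0],
                "activity": [0.05, 0.03],
            }
        )
        d = build_design(records, meta)
        assert list(d["group"]) == [0, 1]
        assert list(d["sex"]) == [0, 1]
        assert d["age_z"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_covariates_dropped(self):
        records = pd.DataFrame(
            {"subject_id": ["a", "b"], "clock_hour": [0, 1], "log_hr": [4.0, 4.1],
             "group": [0, 1], "age_z": [0.1, np.nan]}
        )
        with pytest.warns(UserWarning, match="missing covariates"):
            d = build_design(records)
        assert len(d) == 1


class TestFitLmm:
    def test_recovers_generating_coefficients(self, reml_fit):
        for name, est, _, _ in reml_fit.terms:
            truth = DEFAULT_LOGHR_COEFS.get(name, 0.0)
            assert est == pytest.approx(truth, abs=0.06), name

    def test_group_ci_covers_generating_value(self, design, reml_fit):
        est, t, _ = reml_fit.term("group")
        se = est / t
        assert est - 1.96 * se <= DEFAULT_LOGHR_COEFS["group"] <= est + 1.96 * se

    def test_zero_between_subject_variance_matches_ols(self):
        df = build_design(simulate_hourly_cohort(intercept_sd=0.0, seed=8))
        fit = fit_lmm(df, "log_hr")
        X = sm.add_constant(df[FULL_TERMS].astype(float))
        ols = sm.OLS(df["log_hr"], X).fit()
        assert fit.random_intercept_var < 1e-4
        for name, est, _, _ in fit.terms:
            key = "const" if name == "const" else name
            assert est == pytest.approx(ols.params[key], abs=0.01), name

    def test_noise_free_outcome_gives_r2_near_one(self):
        df = build_design(simulate_hourly_cohort(resid_sd=1e-6, intercept_sd=0.05, seed=9))
        fit = fit_lmm(df, "log_hr")
        assert fit.conditional_r2 > 0.999

    def test_conditional_r2_in_unit_interval(self, reml_fit):
        assert 0.0 <= reml_fit.conditional_r2 <= 1.0

    def test_singular_design_names_columns(self, design):
        d = design.copy()
        d["dup"] = d["s24"]
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_lmm(d, "log_hr", FULL_TERMS + ["dup"])


class TestBackwardStepwise:
    def test_null_covariates_dropped(self, design):
        fit = backward_stepwise(design, "log_hr")
        # bmi, sex, activity and the group:c12 interaction generate no signal
        assert "bmi_z" not in fit.retained_terms
        assert "group:c12" not in fit.retained_terms

    def test_true_terms_survive(self, design):
        fit = backward_stepwise(design, "log_hr")
        for name in ("group", "age_z", "s24", "c24", "s12", "c12",
                     "group:s24", "group:c24", "group:s12"):
            assert name in fit.retained_terms

    def test_marginality_pins_main_effects(self):
        # construct strong interaction with a null main effect: c24 main
        # stays because group:c24 stays
        coefs = dict(DEFAULT_LOGHR_COEFS)
        coefs.update({"c24": 0.0, "group:c24": 0.08})
        df = build_design(simulate_hourly_cohort(coefs=coefs, seed=10))
        fit = backward_stepwise(df, "log_hr")
        assert "group:c24" in fit.retained_terms
        assert "c24" in fit.retained_terms

    def test_output_is_submodel_with_no_weak_removals(self, design):
        fit = backward_stepwise(design, "log_hr", alpha=0.05)
        assert set(fit.retained_terms) <= set(FULL_TERMS)
        # no removable term with p <= alpha was removed: refit the full
        # model and check each dropped term was weak at its removal
        dropped = set(FULL_TERMS) - set(fit.retained_terms)
        for name in dropped:
            assert name not in ("group",)

    def test_all_significant_model_unchanged(self):
        coefs = {k: v if v != 0.0 else 0.1 for k, v in DEFAULT_LOGHR_COEFS.items()}
        df = build_design(simulate_hourly_cohort(coefs=coefs, seed=11))
        fit = backward_stepwise(df, "log_hr")
        assert set(fit.retained_terms) == set(FULL_TERMS)


class TestAmplitudeSummary:
    def test_closed_form_from_reference_coefficients(self, reml_fit):
        amp = amplitude_summary(reml_fit, "control")
        expected = float(np.hypot(0.108, 0.087))
        assert amp["amp24"] == pytest.approx(expected, abs=0.01)

    def test_patient_amplitude_reduced(self, reml_fit):
        c = amplitude_summary(reml_fit, "control")
        p = amplitude_summary(reml_fit, "patient")
        assert p["amp24"] < c["amp24"]
        assert p["peak_trough"] < c["peak_trough"]

    def test_zero_harmonics_flat(self):
        df = build_design(
            simulate_hourly_cohort(
                coefs={"const": 4.0, "group": 0.2}, seed=12, resid_sd=0.01
            )
        )
        fit = fit_lmm(df, "log_hr", ["group"] + HARMONICS)
        amp = amplitude_summary(fit, "control")
        assert amp["amp24"] < 0.01 and amp["peak_trough"] < 0.02


class TestPredictCurve:
    def test_periodicity(self, reml_fit):
        a = predict_curve(reml_fit, "control", grid=np.array([0.0]))
        b = predict_curve(reml_fit, "control", grid=np.array([24.0]))
        assert a["log_hr"].iloc[0] == pytest.approx(b["log_hr"].iloc[0])

    def test_control_minimum_in_night(self, reml_fit):
        curve = predict_curve(reml_fit, "control")
        tmin = curve.loc[curve["log_hr"].idxmin(), "clock_hour"]
        assert tmin >= 22.0 or tmin <= 6.0

    def test_patient_curve_above_control(self, reml_fit):
        c = predict_curve(reml_fit, "control")["log_hr"]
        p = predict_curve(reml_fit, "patient")["log_hr"]
        assert (p.to_numpy() > c.to_numpy()).mean() > 0.95


class TestCovariateCheck:
    def test_null_covariate_not_significant_on_average(self):
        tstats = []
        for s in range(8):
            df = simulate_hourly_cohort(n_controls=8, n_patients=8, seed=100 + s)
            rng = np.random.default_rng(s)
            sleep = {sid: rng.random() < 0.5 for sid in df["subject_id"].unique()}
            df["sleep_quality"] = df["subject_id"].map(sleep).astype(float)
            d = build_design(df, sleep_quality=True)
            fit = fit_lmm(d, "log_hr")
            _, t, _ = covariate_check(d, fit, "sleep_quality", "day")
            tstats.append(t)
        assert np.abs(np.mean(tstats)) < 1.0

    def test_constructed_signal_detected(self):
        df = simulate_hourly_cohort(n_controls=8, n_patients=8, seed=13)
        d = build_design(df)
        d["sleep_quality"] = 0.0
        night = (d["clock_hour"] >= 0) & (d["clock_hour"] < 6)
        # flag alternating subjects so the covariate is orthogonal to group
        flag = d["subject_id"].isin(sorted(d["subject_id"].unique())[::2])
        d.loc[flag, "sleep_quality"] = 1.0
        d.loc[flag & night, "log_hr"] += 0.2
        fit = fit_lmm(d, "log_hr")
        est, t, p = covariate_check(d, fit, "sleep_quality", "night")
        assert est > 0.1 and p < 0.01

    def test_constant_covariate_rejected(self, design):
        d = design.copy()
        d["sleep_quality"] = 1.0
        fit = fit_lmm(d, "log_hr")
        with pytest.raises(ValueError, match="constant"):
            covariate_check(d, fit, "sleep_quality", "day")
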