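"""Group comparisons, responder labelling, and treatment-phase models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cardioday.circadian_model import build_design
from cardioday.clinical_stats import (
    chi_square_2x2,
    group_difference_bootstrap,
    label_responders,
    outlier_filter_hr,
    phase_model,
    response_correlation,
    two_sample_t,
)
from cardioday.synthetic_data import simulate_hourly_cohort


class TestTwoSampleT:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (62.44, 5.33, 77.79, 9.53, -5.62),  # heart rate
            (24.61, 4.24, 30.48, 5.24, -3.48),  # BMI
            (43.62, 12.57, 46.0, 12.29, -0.54),  # age
            (2.0, 2.39, 18.50, 3.08, -16.93),  # QIDS
        ],
    )
    def test_reconstructs_cohort_table(self, m1, s1, m2, s2, expected):
        assert two_sample_t(m1, s1, 16, m2, s2, 16) == pytest.approx(expected, abs=0.01)

    def test_identical_summaries_zero(self):
        assert two_sample_t(10.0, 2.0, 16, 10.0, 2.0, 16) == 0.0

    def test_equal_n_matches_welch(self):
        t_w, _ = stats.ttest_ind_from_stats(5, 1.0, 12, 6, 2.0, 12, equal_var=False)
        assert two_sample_t(5, 1.0, 12, 6, 2.0, 12) == pytest.approx(t_w)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            two_sample_t(5, 0.0, 16, 6, 1.0, 16)


class TestChiSquare:
    def test_smoking_table_reconstruction(self):
        # 12% and 19% of 16 -> 2 and 3 smokers
        assert chi_square_2x2(np.array([[2, 14], [3, 13]])) == pytest.approx(0.237, abs=0.005)

    @pytest.mark.parametrize("table", [[[8, 8], [8, 8]], [[4, 12], [4, 12]]])
    def test_equal_proportions_zero(self, table):
        assert chi_square_2x2(np.array(table)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


class TestLabelResponders:
    @staticmethod
    def _meta(rows):
        return pd.DataFrame(
            [
                {"subject_id": f"P{i}", "group": "patient", "hrsd_baseline": pre, "hrsd_24h_post": post}
                for i, (pre, post) in enumerate(rows)
            ]
        )

    @pytest.mark.parametrize(
        "pre,post,expected",
        [(20, 10, True), (20, 15, False), (20, 14, True)],  # 50%, 25%, exactly 30%
    )
    def test_threshold_semantics(self, pre, post, expected):
        rec = label_responders(self._meta([(pre, post)]))[0]
        assert rec.responder is expected

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(1)
        rows = [(int(p), int(max(p - rng.integers(0, 15), 0))) for p in rng.integers(17, 35, 20)]
        recs = label_responders(self._meta(rows))
        assert len(recs) == 20
        assert all(r.responder == (r.pct_reduction >= 0.30) for r in recs)

    def test_missing_post_excluded_with_warning(self):
        meta = self._meta([(20, 10)])
        meta.loc[1] = {"subject_id": "P9", "group": "patient", "hrsd_baseline": 22, "hrsd_24h_post": np.nan}
        with pytest.warns(UserWarning, match="missing"):
            recs = label_responders(meta)
        assert len(recs) == 1

    def test_controls_ignored(self):
        meta = self._meta([(20, 10)])
        meta.loc[1] = {"subject_id": "C1", "group": "control", "hrsd_baseline": 2, "hrsd_24h_post": np.nan}
        assert len(label_responders(meta)) == 1


class TestOutlierFilter:
    def test_high_value_excluded_at_printed_threshold(self):
        # analysis set with mean ~77.8 whose mean + 2 SD lands near 99.96
        values = np.array([70.0, 72.5, 75.0, 77.0, 79.0, 72.0, 81.0, 74.0, 76.0, 78.0, 73.0, 76.5, 105.0])
        keep, excluded = outlier_filter_hr(values)
        thresh = values.mean() + 2 * values.std(ddof=1)
        assert 95 < thresh < 105
        assert list(excluded) == [12]
        assert keep.sum() == 12

    def test_all_equal_none_excluded(self):
        keep, excluded = outlier_filter_hr(np.full(5, 70.0))
        assert keep.all() and excluded.size == 0

    def test_exactly_mean_plus_two_sd_retained(self):
        x = np.array([0.0, 0.0, 0.0, 0.0])
        x = np.append(x, x.mean() + 2 * x.std(ddof=1))  # degenerate: 0
        keep, _ = outlier_filter_hr(x)
        assert keep.all()


class TestResponseCorrelation:
    def test_monotone_pairs(self):
        out = response_correlation(np.arange(1, 7.0), np.arange(1, 7.0) ** 2)
        assert out["rho"] == pytest.approx(1.0)
        out = response_correlation(np.arange(1, 7.0), -np.arange(1, 7.0))
        assert out["rho"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        out = response_correlation(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert out["rho"] == pytest.approx(0.6)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=40, derandomize=True)
    def test_matches_brute_force_rank_oracle(self, perm):
        x = np.arange(6.0)
        y = np.array(perm, dtype=float)
        d = x - y  # both are already ranks 0..5
        brute = 1 - 6 * np.sum(d**2) / (6 * 35)
        out = response_correlation(x, y)
        assert out["rho"] == pytest.approx(brute, abs=1e-12)

    def test_outlier_filter_changes_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(78, 6, 12)
        y = x * 0.5 + rng.normal(0, 2, 12)  # positive association
        x = np.append(x, 110.0)
        y = np.append(y, y.min() - 5)  # outlier opposing the trend
        with_out = response_correlation(x, y, apply_outlier_filter=False)
        without = response_correlation(x, y, apply_outlier_filter=True)
        assert without["excluded"].size == 1
        assert without["rho"] > with_out["rho"]

    def test_ci_contains_estimate(self):
        out = response_correlation(np.arange(10.0), np.arange(10.0)[::-1], ci_method="bootstrap")
        lo, hi = out["ci"]
        assert lo <= out["rho"] <= hi

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            response_correlation(np.ones(5), np.arange(5.0))


def test_group_difference_bootstrap_brackets_truth():
    rng = np.random.default_rng(3)
    a, b = rng.normal(80, 5, 6), rng.normal(72, 5, 7)
    out = group_difference_bootstrap(a, b, seed=4)
    lo, hi = out["ci"]
    assert lo <= out["difference"] <= hi


class TestPhaseModel:
    @staticmethod
    def _two_phase_design(delta: float, seed: int = 0):
        # same subjects in both phases: the post phase keeps each subject's
        # random intercept and redraws only the residual noise
        pre = simulate_hourly_cohort(n_controls=0, n_patients=10, days=2, seed=seed)
        rng = np.random.default_rng(seed + 1000)
        post = pre.copy()
        post["log_hr"] += rng.normal(0, 0.05, len(post)) - delta
        pre, post = pre.copy(), post
        pre["phase"], post["phase"] = "pre", "post"
        df = pd.concat([pre, post], ignore_index=True)
        return build_design(df)

    def test_recovers_known_phase_drop(self):
        d = self._two_phase_design(delta=0.03, seed=5)
        fit = phase_model(d)
        est, t, p = fit.term("phase_post")
        assert est == pytest.approx(-0.03, abs=0.01)
        assert p < 0.01

    def test_null_phase_effect_small(self):
        ests = []
        for s in range(5):
            d = self._two_phase_design(delta=0.0, seed=20 + s)
            ests.append(phase_model(d).term("phase_post")[0])
        assert abs(np.mean(ests)) < 0.01

    def test_patients_post_vs_controls_keeps_group_gap(self):
        controls = simulate_hourly_cohort(n_controls=10, n_patients=0, days=2, seed=6)
        patients = simulate_hourly_cohort(n_controls=0, n_patients=10, days=2, seed=7)
        patients["log_hr"] -= 0.03  # post-treatment drop smaller than the gap
        controls["phase"], patients["phase"] = "pre", "post"
        d = build_design(pd.concat([controls, patients], ignore_index=True))
        from cardioday.circadian_model import fit_lmm

        fit = fit_lmm(d, "log_hr", ["group", "s24", "c24", "s12", "c12"])
        est, t, p = fit.term("group")
        assert est > 0.1 and p < 0.001

    def test_needs_two_subjects_with_both_phases(self):
        d = self._two_phase_design(delta=0.03, seed=8)
        only_pre = d[d["phase"] == "pre"]
        with pytest.raises(ValueError, match="both phases"):
            phase_model(only_pre)
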