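"""Competing risks: Aalen-Johansen, CSH Cox fits, profile prediction, RRs."""

import numpy as np
import pandas as pd
import pytest

import bcmort as b
from bcmort.competing import AGE_GROUPS, CompetingRisksError
from conftest import constant_hazard_cohort, make_cohort_frame
from oracles import cox_mle_1cov, cumulative_incidence_enumeration


class TestAalenJohansen:
    def test_no_events_gives_flat_curve(self):
        df = make_cohort_frame([("a", 50, 2005, "I", "unknown", 10.0, None)] * 3)
        curve = b.aalen_johansen(df)
        assert np.all(curve.survival == 1.0)
        assert all(np.all(p == 0.0) for p in curve.p_cause.values())

    def test_empty_cohort_rejected(self):
        with pytest.raises(CompetingRisksError):
            b.aalen_johansen(make_cohort_frame([]).reindex(columns=b.cohort.COHORT_COLUMNS))

    def test_five_subject_toy_matches_hand_enumeration(self, toy5):
        curve = b.aalen_johansen(toy5)
        records = [(1.0, "BC"), (2.0, "CVD"), (3.0, None), (4.0, "BC"), (5.0, "OtherCancer")]
        times, probs, surv = cumulative_incidence_enumeration(records, b.CAUSE4)
        assert curve.times.tolist() == times
        for i in range(len(times)):
            assert curve.survival[i] == pytest.approx(surv[i], abs=1e-12)
            for c in b.CAUSE4:
                assert curve.p_cause[c][i] == pytest.approx(probs[i][c], abs=1e-12)

    def test_normalisation_identity_everywhere(self, small_sim):
        _, cohort, _ = small_sim
        curve = b.aalen_johansen(cohort)
        assert np.abs(curve.survival + curve.total - 1.0).max() < 1e-10

    def test_single_cause_collapses_to_one_minus_km(self):
        from lifelines import KaplanMeierFitter

        df = constant_hazard_cohort([0.08, 0, 0, 0], n=400, seed=21)
        curve = b.aalen_johansen(df)
        km = KaplanMeierFitter().fit(df["follow_time"], df["event"])
        km_surv = km.survival_function_at_times(curve.times).to_numpy()
        assert curve.p_cause["BC"] == pytest.approx(1 - km_surv, abs=1e-12)
        for c in ("OtherCancer", "CVD", "OtherCauses"):
            assert np.all(curve.p_cause[c] == 0.0)

    def test_merged_causes_reproduce_all_cause_mortality(self):
        df = constant_hazard_cohort([0.04, 0.02, 0.02, 0.01], n=300, seed=22)
        curve = b.aalen_johansen(df)
        merged = df.copy()
        merged["cause_code"] = np.where(merged["event"], "C50", None)
        collapsed = b.aalen_johansen(merged)
        assert collapsed.p_cause["BC"] == pytest.approx(1 - curve.survival, abs=1e-12)

    def test_estimates_and_variances_match_cmprsk_reference(self):
        # fixture regenerated deterministically; reference values computed once
        # with R cmprsk::cuminc (Gray) on the same data
        rng = np.random.default_rng(11)
        n = 60
        t = np.round(rng.exponential(6, n), 3)
        cause = rng.choice([0, 1, 2], n, p=[0.5, 0.3, 0.2])
        ev = t <= 10
        ft = np.minimum(t, 10)
        codes = {1: "C50", 2: "I21"}
        df = make_cohort_frame(
            [
                (str(i), 50, 2005, "I", "positive", ft[i], codes.get(cause[i]) if ev[i] else None)
                for i in range(n)
            ]
        )
        curve = b.aalen_johansen(df)
        expected_est = {
            2: {"BC": 0.11650166, "CVD": 0.05327945},
            5: {"BC": 0.22968827, "CVD": 0.11897635},
            8: {"BC": 0.33253070, "CVD": 0.11897635},
        }
        expected_var = {
            2: {"BC": 0.0020585566, "CVD": 0.0009181982},
            5: {"BC": 0.003879073, "CVD": 0.002173797},
            8: {"BC": 0.006095177, "CVD": 0.002173797},
        }
        for T, vals in expected_est.items():
            at = curve.at(T)
            i = np.searchsorted(curve.times, T, side="right") - 1
            for c, v in vals.items():
                assert at[c] == pytest.approx(v, abs=1e-8)
                # our Aalen-type variance is a close (not identical) variant
                # of the counting-process form cmprsk uses
                assert curve.se_cause[c][i] ** 2 == pytest.approx(expected_var[T][c], rel=0.06)


class TestAgeGroup:
    @pytest.mark.parametrize(
        "age, grp", [(15, "<=49"), (49, "<=49"), (50, "50-68"), (68, "50-68"), (69, ">=69"), (84, ">=69")]
    )
    def test_boundaries(self, age, grp):
        assert b.age_group(age) == grp

    @pytest.mark.parametrize("age", [14, 85, -1])
    def test_out_of_range_rejected(self, age):
        with pytest.raises(CompetingRisksError):
            b.age_group(age)


class TestCSHCox:
    def test_identical_groups_give_null_coefficient(self):
        rows = []
        for i, (t, c) in enumerate([(1.0, "C50"), (2.0, "C50"), (3.0, None), (4.0, "C50")]):
            rows.append((f"p{i}", 50, 2005, "I", "positive", t, c))
            rows.append((f"n{i}", 50, 2005, "I", "negative", t, c))
        fit = b.fit_csh_cox(make_cohort_frame(rows), ["hr_status"], "BC")
        assert abs(fit.coefficients.loc["hr_negative", "coef"]) < 1e-6

    def test_six_subject_toy_matches_partial_likelihood_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 0]
        x = [1, 0, 1, 0, 1, 0]
        df = make_cohort_frame(
            [
                (str(i), 50, 2005, "I", "negative" if x[i] else "positive", times[i], "C50" if events[i] else None)
                for i in range(6)
            ]
        )
        fit = b.fit_csh_cox(df, ["hr_status"], "BC")
        beta_oracle = cox_mle_1cov(times, events, x)
        assert fit.coefficients.loc["hr_negative", "coef"] == pytest.approx(beta_oracle, abs=1e-6)

    def test_hazard_ratio_recovery_at_n_5000(self):
        lam_pos = np.array([0.012, 0.003, 0.003, 0.004])
        pos = constant_hazard_cohort(lam_pos, n=4000, seed=31, hr="positive")
        neg = constant_hazard_cohort(lam_pos * [2, 1, 1, 1], n=1000, seed=32, hr="negative")
        neg["id"] = "n" + neg["id"]
        df = pd.concat([pos, neg], ignore_index=True)
        fit = b.fit_csh_cox(df, ["hr_status"], "BC")
        beta = fit.coefficients.loc["hr_negative", "coef"]
        se = fit.coefficients.loc["hr_negative", "se"]
        assert abs(beta - np.log(2.0)) < 3 * se

    def test_no_events_of_cause_raises_naming_cause(self):
        df = constant_hazard_cohort([0.05, 0, 0, 0], n=50, seed=33)
        with pytest.raises(CompetingRisksError, match="CVD"):
            b.fit_csh_cox(df, ["age"], "CVD")

    def test_unknown_covariate_rejected(self, toy5):
        with pytest.raises(CompetingRisksError):
            b.fit_csh_cox(toy5, ["tumour_grade"], "BC")


class TestPredictCIM:
    def test_null_model_equals_nonparametric(self):
        df = constant_hazard_cohort([0.05, 0.01, 0.02, 0.02], n=300, seed=5)
        fits = [b.fit_csh_cox(df, [], c) for c in b.CAUSE4]
        pred = b.predict_cim(fits, {})
        aj = b.aalen_johansen(df)
        assert np.array_equal(pred.times, aj.times)
        for c in b.CAUSE4:
            assert np.abs(pred.p_cause[c] - aj.p_cause[c]).max() < 1e-8
        assert np.abs(pred.survival - aj.survival).max() < 1e-8

    def test_closed_form_recovery_constant_hazards(self):
        lam = np.array([0.05, 0.01, 0.02, 0.02])
        df = constant_hazard_cohort(lam, n=5000, seed=41)
        fits = [b.fit_csh_cox(df, [], c) for c in b.CAUSE4]
        pred = b.predict_cim(fits, {})
        total = lam.sum()
        at10 = pred.at(10.0)
        for k, c in enumerate(b.CAUSE4):
            p_true = lam[k] / total * -np.expm1(-10 * total)
            se = np.sqrt(p_true * (1 - p_true) / 5000)
            assert abs(at10[c] - p_true) < 3 * se, c

    def test_total_probability_identity_at_horizon(self):
        df = constant_hazard_cohort([0.05, 0.01, 0.02, 0.02], n=400, seed=42)
        fits = [b.fit_csh_cox(df, [], c) for c in b.CAUSE4]
        pred = b.predict_cim(fits, {})
        assert b.total_probability(pred, 10.0) == pytest.approx(1 - pred.at(10.0)["survival"], abs=1e-12)

    def test_profile_scales_hazards(self):
        pos = constant_hazard_cohort([0.01, 0.005, 0.005, 0.005], n=2500, seed=43, hr="positive")
        neg = constant_hazard_cohort([0.06, 0.005, 0.005, 0.005], n=2500, seed=44, hr="negative")
        neg["id"] = "n" + neg["id"]
        df = pd.concat([pos, neg], ignore_index=True)
        fits = [b.fit_csh_cox(df, ["hr_status"], c) for c in b.CAUSE4]
        for flag, lam_bc in ((0.0, 0.01), (1.0, 0.06)):
            lam = np.array([lam_bc, 0.005, 0.005, 0.005])
            pred = b.predict_cim(fits, {"hr_negative": flag})
            p_true = lam[0] / lam.sum() * -np.expm1(-10 * lam.sum())
            se = np.sqrt(p_true * (1 - p_true) / 2500)
            assert abs(pred.at(10.0)["BC"] - p_true) < 3 * se

    def test_missing_profile_covariate_rejected(self):
        df = constant_hazard_cohort([0.05, 0.01, 0.01, 0.01], n=200, seed=45)
        df.loc[::2, "hr_status"] = "negative"
        fits = [b.fit_csh_cox(df, ["hr_status"], "BC")]
        with pytest.raises(CompetingRisksError, match="hr_negative"):
            b.predict_cim(fits, {})

    def test_bootstrap_attaches_standard_errors(self):
        df = constant_hazard_cohort([0.05, 0.02, 0.02, 0.02], n=250, seed=46)
        curve = b.bootstrap_cim(df, [], {}, n_boot=25, seed=1)
        for c in b.CAUSE4:
            assert curve.se_cause[c].shape == curve.times.shape
            assert np.nanmax(curve.se_cause[c]) > 0


class TestRelativeRisk:
    def test_equal_hazards_give_unit_rr(self):
        pos = constant_hazard_cohort([0.02, 0.01, 0.01, 0.01], n=2000, seed=51, hr="positive")
        neg = constant_hazard_cohort([0.02, 0.01, 0.01, 0.01], n=2000, seed=52, hr="negative")
        neg["id"] = "n" + neg["id"]
        rrs = b.relative_risk(pd.concat([pos, neg], ignore_index=True), "I")
        for out in rrs.values():
            assert out.ci95[0] <= 1.0 <= out.ci95[1]

    def test_empty_stratum_rejected(self, toy5):
        with pytest.raises(CompetingRisksError):
            b.relative_risk(toy5, "IV")

    def test_categorical_adjustment_mode(self):
        pos = constant_hazard_cohort([0.03, 0.01, 0.01, 0.01], n=1500, seed=53, hr="positive")
        neg = constant_hazard_cohort([0.06, 0.01, 0.01, 0.01], n=1500, seed=54, hr="negative")
        neg["id"] = "n" + neg["id"]
        rrs = b.relative_risk(pd.concat([pos, neg], ignore_index=True), "I", adjust="categorical")
        assert rrs["bc"].rr == pytest.approx(2.0, rel=0.35)
        with pytest.raises(CompetingRisksError):
            b.relative_risk(pos, "I", adjust="splines")


class TestTotalProbability:
    def test_sum_of_printed_style_probabilities(self):
        curve = _step_curve({"BC": 0.0181, "OtherCancer": 0.0371, "CVD": 0.0121, "OtherCauses": 0.0331})
        assert 100 * b.total_probability(curve, 10.0) == pytest.approx(10.04)

    def test_zero_curve(self):
        curve = _step_curve({c: 0.0 for c in b.CAUSE4})
        assert b.total_probability(curve, 10.0) == 0.0

    def test_negative_time_rejected(self):
        curve = _step_curve({c: 0.01 for c in b.CAUSE4})
        with pytest.raises(CompetingRisksError):
            b.total_probability(curve, -1.0)


def _step_curve(p10):
    total = sum(p10.values())
    return b.CIMCurve(
        times=np.array([10.0]),
        p_cause={c: np.array([v]) for c, v in p10.items()},
        survival=np.array([1.0 - total]),
    )
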