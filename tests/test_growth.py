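"""BMI, LMS Z-scores and conditional relative weight gain."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grslife.growth import (
    add_bmi_zscores,
    cohort_summary,
    compute_bmi,
    conditional_weight_gain,
    default_periods,
    lms_inverse,
    lms_zscore,
    select_period_measurements,
)


def lms_ref(L=-1.6, M=16.0, S=0.11):
    return pd.DataFrame({
        "sex": ["M", "M", "F", "F"],
        "age": [0.0, 20.0, 0.0, 20.0],
        "L": [L] * 4, "M": [M] * 4, "S": [S] * 4,
    })


class TestBmi:
    def test_cohort_18y_values(self):
        # printed 18-y means: 59.4 kg / 170.8 cm (male), 59.5 kg / 159.7 cm (female)
        assert compute_bmi(59.4, 170.8) == pytest.approx(20.36, abs=0.005)
        assert compute_bmi(59.5, 159.7) == pytest.approx(23.33, abs=0.005)

    def test_unit_case(self):
        assert compute_bmi(1.0, 100.0) == 1.0

    def test_non_positive_errors(self):
        with pytest.raises(ValueError):
            compute_bmi(0.0, 100.0)
        with pytest.raises(ValueError):
            compute_bmi(50.0, -1.0)


class TestLmsZscore:
    def test_median_maps_to_zero(self):
        assert lms_zscore(16.0, "M", 5.0, lms_ref()) == pytest.approx(0.0, abs=1e-12)

    def test_unit_L_closed_form(self):
        ref = lms_ref(L=1.0, M=20.0, S=0.1)
        assert lms_zscore(20.0 * 1.1, "M", 5.0, ref) == pytest.approx(1.0, abs=1e-10)

    def test_box_cox_formula_value(self):
        # ((20/16)^-1.6 - 1) / (-1.6 * 0.11), evaluated independently
        expected = (np.power(20.0 / 16.0, -1.6) - 1.0) / (-1.6 * 0.11)
        assert lms_zscore(20.0, "M", 5.0, lms_ref()) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.70596, abs=1e-5)

    def test_age_outside_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            lms_zscore(16.0, "M", 25.0, lms_ref())

    def test_non_positive_measurement_errors(self):
        with pytest.raises(ValueError):
            lms_zscore(0.0, "M", 5.0, lms_ref())

    @given(st.floats(-4, 4), st.floats(-2, 2, exclude_min=False),
           st.floats(10, 25), st.floats(0.05, 0.2))
    def test_round_trip(self, z, L, M, S):
        ref = lms_ref(L=L, M=M, S=S)
        if abs(L) > 1e-12 and 1.0 + L * S * z <= 1e-6:
            return  # outside the Box-Cox domain for this (L, S)
        x = lms_inverse(z, "F", 10.0, ref)
        assert lms_zscore(x, "F", 10.0, ref) == pytest.approx(z, abs=1e-10)

    def test_implausible_values_flagged_but_kept(self):
        ref = lms_ref(L=1.0, M=16.0, S=0.1)
        anthro = pd.DataFrame({
            "subject_id": ["a", "b"], "sex": ["M", "M"],
            "age_years": [5.0, 5.0], "weight_kg": [16.0, 60.0],
            "height_cm": [100.0, 100.0],
        })
        out = add_bmi_zscores(anthro, ref)
        assert out["implausible"].tolist() == [False, True]
        assert len(out) == 2


class TestSelectMeasurements:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "sex", "age_years",
                                           "weight_kg", "height_cm"])

    def test_exact_age_records_chosen_verbatim(self):
        t = self.make([("a", "M", 2.0, 12.0, 85.0), ("a", "M", 5.0, 18.0, 105.0)])
        wide = select_period_measurements(t, [2.0, 5.0])
        assert wide.loc[0, "weight_2"] == 12.0
        assert wide.loc[0, "height_5"] == 105.0

    def test_closest_record_within_tolerance_wins(self):
        t = self.make([("a", "M", 1.9, 11.0, 84.0), ("a", "M", 2.2, 12.5, 86.0)])
        wide = select_period_measurements(t, [2.0])
        assert wide.loc[0, "weight_2"] == 11.0  # 1.9 is closer than 2.2

    def test_equidistant_tie_goes_to_earlier_record(self):
        t = self.make([("a", "M", 1.8, 11.0, 84.0), ("a", "M", 2.2, 12.5, 86.0)])
        wide = select_period_measurements(t, [2.0])
        assert wide.loc[0, "weight_2"] == 11.0

    def test_gap_leaves_anchor_empty(self):
        t = self.make([("a", "M", 0.0, 3.2, 50.0), ("b", "M", 2.0, 12.0, 85.0)])
        wide = select_period_measurements(t, [0.0, 2.0]).set_index("subject_id")
        assert np.isnan(wide.loc["a", "weight_2"])
        assert np.isnan(wide.loc["b", "weight_0"])


class TestConditionalGain:
    @staticmethod
    def simulate_wide(n=300, seed=0):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.uniform(size=n) < 0.5, "M", "F")
        w0 = rng.normal(3.2, 0.4, n)
        h2 = rng.normal(85, 3, n)
        w2 = 9.0 + 0.5 * w0 + 0.02 * h2 + rng.normal(0, 1.0, n)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "sex": sex,
            "weight_0": w0, "height_2": h2, "weight_2": w2,
        })

    PERIOD = default_periods()[0]  # infancy: weight_0 + height_2 -> weight_2

    def test_sr_mean_zero_sd_one_within_sex(self):
        gains = conditional_weight_gain(self.simulate_wide(), self.PERIOD)
        for _, sub in gains.groupby("sex"):
            assert abs(sub["sr"].mean()) < 1e-8
            assert abs(sub["sr"].std(ddof=1) - 1.0) < 1e-8

    def test_sr_orthogonal_to_predictors(self):
        wide = self.simulate_wide(seed=1)
        gains = conditional_weight_gain(wide, self.PERIOD)
        merged = wide.merge(gains, on=["subject_id", "sex"])
        for sex, sub in merged.groupby("sex"):
            for col in ("weight_0", "height_2"):
                assert abs(np.corrcoef(sub["sr"], sub[col])[0, 1]) < 1e-8

    def test_sr_invariant_to_predictor_units(self):
        wide = self.simulate_wide(seed=2)
        scaled = wide.copy()
        scaled["weight_0"] *= 1000.0  # kg -> g
        g1 = conditional_weight_gain(wide, self.PERIOD)
        g2 = conditional_weight_gain(scaled, self.PERIOD)
        np.testing.assert_allclose(g1["sr"], g2["sr"], atol=1e-8)

    def test_independent_weights_give_height_adjusted_standardized_end_weight(self):
        """With end weight independent of priors, SR matches the analytic
        standardized residual of weight on height alone (oracle by direct
        regression)."""
        rng = np.random.default_rng(3)
        n = 2000
        wide = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": ["M"] * n,
            "weight_0": rng.normal(3.2, 0.4, n),
            "height_2": rng.normal(85, 3, n),
            "weight_2": rng.normal(12, 1.5, n),
        })
        gains = conditional_weight_gain(wide, self.PERIOD)
        X = np.column_stack([np.ones(n), wide["weight_0"], wide["height_2"]])
        beta, *_ = np.linalg.lstsq(X, wide["weight_2"], rcond=None)
        resid = wide["weight_2"] - X @ beta
        oracle = resid / resid.std(ddof=1)
        np.testing.assert_allclose(gains.sort_values("subject_id")["sr"].to_numpy(),
                                   oracle[np.argsort(wide["subject_id"])], atol=1e-10)

    def test_collinear_design_errors_with_column_names(self):
        wide = self.simulate_wide(seed=4)
        wide["height_2"] = 2.0 * wide["weight_0"]
        with pytest.raises(ValueError, match="height_2"):
            conditional_weight_gain(wide, self.PERIOD)

    def test_too_few_complete_cases_errors(self):
        wide = self.simulate_wide(seed=5).iloc[:3]
        with pytest.raises(ValueError, match="complete"):
            conditional_weight_gain(wide, self.PERIOD)


class TestPeriods:
    def test_default_period_structure(self):
        periods = default_periods()
        assert [p.name for p in periods] == [
            "infancy", "early_childhood", "mid_childhood", "adolescence"
        ]
        adol = periods[3]
        assert adol.start_age == 8.0 and adol.end_age == 15.0
        assert adol.prior_weight_ages == (0.0, 2.0, 5.0, 8.0)
        assert adol.prior_height_ages == (2.0, 5.0, 8.0)

    def test_null_cohort_gains_weakly_correlated_across_periods(self, cohort):
        """Non-overlapping periods' SRs decorrelate on generated data."""
        periods = default_periods()
        anchors = sorted({a for p in periods for a in p.anchor_ages})
        wide = select_period_measurements(cohort["truth"], anchors)
        gains = {p.name: conditional_weight_gain(wide, p) for p in periods}
        inf = gains["infancy"].set_index("subject_id")["sr"]
        mid = gains["mid_childhood"].set_index("subject_id")["sr"]
        both = pd.concat([inf, mid], axis=1, keys=["a", "b"]).dropna()
        assert abs(np.corrcoef(both["a"], both["b"])[0, 1]) < 0.25


class TestCohortSummary:
    def test_constant_column_zero_sd_and_counts(self, cohort):
        s = cohort_summary(cohort["truth"], cohort["lms"], ages=[5.0])
        row = s[(s["age"] == 5.0) & (s["variable"] == "bmi")].iloc[0]
        truth5 = cohort["truth"][cohort["truth"]["age_years"] == 5.0]
        assert row["n_M"] == (truth5["sex"] == "M").sum()
        assert row["n_F"] == (truth5["sex"] == "F").sum()

    def test_identical_sexes_give_large_p(self):
        rng = np.random.default_rng(6)
        n = 400
        vals = rng.normal(18, 2, n // 2)
        t = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": ["M"] * (n // 2) + ["F"] * (n // 2),
            "age_years": 5.0,
            "weight_kg": np.r_[vals, vals],
            "height_cm": 100.0,
        })
        s = cohort_summary(t, ages=[5.0])
        w = s[s["variable"] == "weight"].iloc[0]
        assert w["p_MF"] > 0.99
        h = s[s["variable"] == "height"].iloc[0]
        assert h["sd_M"] == 0.0
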