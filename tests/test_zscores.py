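"""LMS z-scoring, interpolation, conditional weight-for-length, preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import growthcontrasts as gc
from growthcontrasts.zscores import lookup_lms


class TestLms:
    def test_median_maps_to_zero_for_any_L(self):
        for L in (-1.0, 0.0, 0.5, 1.0):
            assert gc.lms_z(10.0, L, 10.0, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_L_equals_one_closed_form(self):
        assert gc.lms_z(10.0 * 1.1, 1.0, 10.0, 0.1) == pytest.approx(1.0, abs=1e-12)

    def test_box_cox_example(self):
        # ((1.1)^0.5 - 1)/(0.5*0.1)
        assert gc.lms_z(11.0, 0.5, 10.0, 0.1) == pytest.approx(0.9761769634, abs=1e-9)

    def test_continuous_in_L_at_zero(self):
        assert gc.lms_z(11.0, 1e-9, 10.0, 0.1) == pytest.approx(
            np.log(1.1) / 0.1, abs=1e-6
        )

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            gc.lms_z(-1.0, 1.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            gc.lms_z(1.0, 1.0, 10.0, -0.1)

    @given(
        x=st.floats(0.5, 30.0),
        L=st.floats(-2.0, 2.0),
        S=st.floats(0.01, 0.3),
    )
    def test_round_trip_and_monotonicity(self, x, L, S):
        M = 10.0
        z = gc.lms_z(x, L, M, S)
        assert gc.lms_inverse(z, L, M, S) == pytest.approx(x, abs=1e-10 * max(1, x))
        eps = 1e-4
        assert gc.lms_z(x + eps, L, M, S) > z


class TestInterpolation:
    def test_bracketing_pair_interpolates(self):
        out = gc.interpolate_to_targets([2.5, 3.5], [0.6, 0.8], targets=(0, 1.5, 3, 6, 12, 24))
        assert out[2] == pytest.approx(0.7, abs=1e-12)

    def test_observation_at_target_returned_unchanged(self):
        out = gc.interpolate_to_targets([0.0, 3.0], [0.1, 0.9])
        assert out[0] == 0.1 and out[2] == 0.9

    def test_window_rule_carries_single_and_leaves_missing(self):
        # 2.9 is inside the 3 m window; nothing is near 12 m
        out = gc.interpolate_to_targets([2.9], [0.4])
        assert out[2] == 0.4
        assert np.isnan(out[4])

    def test_duplicate_ages_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gc.interpolate_to_targets([3.0, 3.0], [0.1, 0.2])

    @given(
        slope=st.floats(-1, 1),
        intercept=st.floats(-2, 2),
    )
    def test_exact_for_affine_z(self, slope, intercept):
        # every target has an in-window bracketing pair (or an exact hit)
        ages = np.array([0.0, 1.0, 2.0, 2.5, 3.5, 5.0, 7.0, 11.0, 13.0, 23.0, 25.0])
        vals = slope * ages + intercept
        out = gc.interpolate_to_targets(ages, vals)
        np.testing.assert_allclose(
            out, slope * np.array(gc.TARGET_AGES) + intercept, atol=1e-9
        )


class TestWeightForLength:
    def test_pearson_hand_example(self):
        assert gc.wl_correlation([-1, 0, 1], [-1, 1, 0]) == pytest.approx(0.5, abs=1e-12)

    def test_independent_columns_near_zero(self, rng):
        zw, zl = rng.standard_normal((2, 100_000))
        assert abs(gc.wl_correlation(zw, zl)) < 0.01

    def test_collinear_input_rejected(self):
        z = [0.1, 0.5, -0.3, 0.2]
        with pytest.raises(ValueError, match="degenerate"):
            gc.wl_correlation(z, z)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gc.wl_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_conditional_formula(self):
        assert gc.weight_for_length_z(1.0, 0.5, 0.6) == pytest.approx(0.875, abs=1e-12)
        assert gc.weight_for_length_z(0.7, 0.5, 0.0) == 0.7
        assert gc.weight_for_length_z(0.3, 0.5, 0.6) == pytest.approx(0.0, abs=1e-12)

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc.weight_for_length_z(1.0, 0.5, 1.0)

    def test_unit_variance_under_bivariate_normal(self, rng):
        r = 0.6
        zl = rng.standard_normal(100_000)
        zw = r * zl + np.sqrt(1 - r * r) * rng.standard_normal(100_000)
        cond = gc.weight_for_length_z(zw, zl, r)
        assert np.std(cond, ddof=1) == pytest.approx(1.0, abs=0.02)


class TestEmpiricalReference:
    def test_simple_three_value_cell_mean_and_cv(self):
        rec = pd.DataFrame(
            {
                "child_id": range(3),
                "sex": 0,
                "gest_age": 40.0,
                "age_months": 1.0,
                "weight_kg": [3.0, 4.0, 5.0],
                "length_cm": [49.0, 50.0, 51.0],
            }
        )
        ref = gc.fit_empirical_reference(rec, age_bins=[0, 2], min_cell=3)
        row = ref[ref.measure == "weight"].iloc[0]
        assert row.M == pytest.approx(4.0) and row.S == pytest.approx(0.25)

    def test_underpopulated_cell_named(self):
        rec = pd.DataFrame(
            {
                "child_id": range(5),
                "sex": 0,
                "gest_age": 40.0,
                "age_months": 1.0,
                "weight_kg": [3.0, 4.0, 5.0, 4.5, 3.5],
                "length_cm": 50.0,
            }
        )
        with pytest.raises(ValueError, match=r"sex=0.*weight"):
            gc.fit_empirical_reference(rec, age_bins=[0, 2], min_cell=20)

    def test_degenerate_cell_rejected(self):
        rec = pd.DataFrame(
            {
                "child_id": range(25),
                "sex": 0,
                "gest_age": 40.0,
                "age_months": 1.0,
                "weight_kg": 4.0,
                "length_cm": np.linspace(48, 52, 25),
            }
        )
        with pytest.raises(ValueError, match="S = 0"):
            gc.fit_empirical_reference(rec, age_bins=[0, 2])

    def test_self_standardisation(self, rng):
        n = 200
        rec = pd.DataFrame(
            {
                "child_id": range(n),
                "sex": 0,
                "gest_age": 40.0,
                "age_months": 1.0,
                "weight_kg": rng.normal(4.5, 0.5, n).clip(2, 8),
                "length_cm": rng.normal(53, 2, n).clip(45, 60),
            }
        )
        ref = gc.fit_empirical_reference(rec, age_bins=[0, 2])
        L, M, S = lookup_lms(ref, 0, "weight", np.ones(n))
        z = gc.lms_z(rec["weight_kg"], L, M, S)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestClassifyOverweight:
    def test_boundary_is_inclusive(self, cutoffs):
        row = cutoffs[(cutoffs.sex == 0) & (cutoffs.age_years == 8.0)].iloc[0]
        c = float(row.bmi_cutoff)
        height = 130.0
        w_at = c * (height / 100) ** 2
        assert gc.classify_overweight(w_at, height, 8.0, 0, cutoffs)[0] == 1
        assert gc.classify_overweight(w_at - 0.01, height, 8.0, 0, cutoffs)[0] == 0

    def test_bmi_arithmetic_and_interpolation(self, cutoffs):
        # 25 kg at 125 cm -> BMI 16.0, below any cutoff in the table
        assert gc.classify_overweight(25.0, 125.0, 8.25, 1, cutoffs)[0] == 0

    def test_age_outside_table_rejected(self, cutoffs):
        with pytest.raises(ValueError, match="range"):
            gc.classify_overweight(25.0, 125.0, 12.0, 0, cutoffs)


class TestPrepare:
    def test_zero_jitter_round_trip(self, cohort900, reference):
        raw = gc.simulate_unbalanced_raw(cohort900, reference, 0.0, seed=5)
        prep = gc.prepare(
            raw, reference, outcome=cohort900.data[["child_id", "outcome"]]
        )
        zc = ["z0", "z1p5", "z3", "z6", "z12", "z24"]
        a = cohort900.data.sort_values("child_id")[zc].to_numpy()
        b = prep.data.sort_values("child_id")[zc].to_numpy()
        assert np.abs(a - b).max() < 1e-8
        assert not prep.data[zc].isna().any().any()

    def test_child_without_12m_window_excluded_and_counted(self, cohort900, reference):
        raw = gc.simulate_unbalanced_raw(cohort900, reference, 0.0, seed=5)
        victim = raw["child_id"].iloc[0]
        raw = raw[~((raw.child_id == victim) & (raw.age_months == 12.0))]
        prep = gc.prepare(
            raw, reference, outcome=cohort900.data[["child_id", "outcome"]]
        )
        assert victim not in set(prep.data["child_id"])
        assert prep.dropped["incomplete_exposures"] == 1
        assert prep.n == len(cohort900.data) - 1

    def test_row_count_bookkeeping_with_k_incomplete(self, cohort900, reference):
        raw = gc.simulate_unbalanced_raw(cohort900, reference, 0.0, seed=5)
        victims = raw["child_id"].unique()[:7]
        raw = raw[~(raw.child_id.isin(victims) & (raw.age_months == 6.0))]
        prep = gc.prepare(
            raw, reference, outcome=cohort900.data[["child_id", "outcome"]]
        )
        assert prep.n == len(cohort900.data) - 7

    def test_jittered_cohort_recovers_generating_z(self, cohort900, reference):
        raw = gc.simulate_unbalanced_raw(cohort900, reference, 0.25, seed=5)
        prep = gc.prepare(
            raw, reference, outcome=cohort900.data[["child_id", "outcome"]]
        )
        zc = ["z0", "z1p5", "z3", "z6", "z12", "z24"]
        a = cohort900.data.sort_values("child_id").reset_index()
        b = prep.data.sort_values("child_id").reset_index()
        assert len(b) > 0.95 * len(a)
        a = a[a.child_id.isin(b.child_id)]
        for c in zc:
            r = np.corrcoef(a[c], b[c])[0, 1]
            assert r > 0.95

    def test_missing_outcome_requires_some_route(self, cohort900, reference):
        raw = gc.simulate_unbalanced_raw(cohort900, reference, 0.0, seed=5)
        with pytest.raises(ValueError, match="outcome"):
            gc.prepare(raw, reference)
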