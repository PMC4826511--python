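"""Two-step residual scores, SD-standardisation and scale comparisons."""

import numpy as np
import pandas as pd
import pytest

import growthcontrasts as gc
from growthcontrasts.residuals import first_step_terms
from growthcontrasts.schedule import z_columns

ZC = z_columns()


def three_point_Z():
    Z = pd.DataFrame(0.0, index=range(3), columns=ZC)
    Z["z0"] = [-1.0, 0.0, 1.0]
    Z["z1p5"] = [-0.5, 0.3, 0.9]
    return Z


class TestFirstStep:
    def test_hand_ols_three_points(self):
        s = gc.residual_scores(three_point_Z(), "a", 1)
        np.testing.assert_allclose(
            s.scores, [-0.0333333333, 0.0666666667, -0.0333333333], atol=1e-9
        )
        assert s.sd == pytest.approx(0.057735, abs=1e-5)

    def test_perfect_prediction_gives_zero_residuals(self, Z900):
        Z = Z900.copy()
        Z["z1p5"] = Z["z0"]
        s = gc.residual_scores(Z, "a", 1)
        assert np.abs(s.scores).max() < 1e-12

    @pytest.mark.parametrize("contrast,period", [
        ("a", 3), ("b", 0), ("b", 5), ("c", 2), ("d", 4), ("e", 1),
    ])
    def test_residual_mean_is_zero(self, Z900, contrast, period):
        s = gc.residual_scores(Z900, contrast, period)
        assert abs(s.scores.mean()) < 1e-12

    def test_first_step_terms_follow_contrast_definitions(self):
        assert first_step_terms("a", 2) == ("z3", ["z0", "z1p5"])
        assert first_step_terms("b", 2) == ("z0", ["d_0_1p5", "d_1p5_3"])
        resp, cond = first_step_terms("c", 1)
        assert resp == "d_0_1p5" and "z0" in cond and "d_0_1p5" not in cond
        assert first_step_terms("d", 1) == ("d_0_1p5", ["z1p5"])
        resp, cond = first_step_terms("e", 5)
        assert resp == "d_12_24" and cond[-1] == "z24" and "d_12_24" not in cond


class TestStandardisation:
    def test_hand_example(self):
        s = gc.standardise_scores(gc.residual_scores(three_point_Z(), "a", 1))
        np.testing.assert_allclose(s.scores, [-0.57735, 1.154701, -0.57735], atol=1e-5)
        assert s.scores.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, Z900):
        s1 = gc.standardise_scores(gc.residual_scores(Z900, "c", 3))
        s2 = gc.standardise_scores(s1)
        pd.testing.assert_series_equal(s1.scores, s2.scores)

    def test_zero_sd_rejected(self, Z900):
        Z = Z900.copy()
        Z["z1p5"] = Z["z0"]
        s = gc.residual_scores(Z, "a", 1)
        with pytest.raises(ValueError, match="zero"):
            gc.standardise_scores(s)

    def test_transformer_standardised_output_unit_sd(self, Z900):
        t = gc.ResidualScoreTransformer("a", 2, standardise=True)
        out = t.fit_transform(Z900).ravel()
        assert np.std(out, ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestTwoStep:
    def test_standardised_coefficient_is_unstandardised_times_sd(self, Z900):
        y = Z900["outcome"]
        raw = gc.residual_scores(Z900, "a", 3)
        std = gc.standardise_scores(raw)
        r1 = gc.two_step_fit(raw, y)
        r2 = gc.two_step_fit(std, y)
        assert r2["estimate"] == pytest.approx(r1["estimate"] * raw.sd, abs=1e-8)
        # Wald z (hence p) is invariant to rescaling the single regressor
        z1 = r1["estimate"] / r1["se"]
        z2 = r2["estimate"] / r2["se"]
        assert z1 == pytest.approx(z2, abs=1e-10)
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-12)

    def test_identity_link_two_step_equals_one_step(self):
        """With a continuous outcome and no covariates, the residual fit
        reproduces the one-step conditional-growth coefficient exactly."""
        Z = gc.simulate_balanced_z(700, seed=21)
        rng = np.random.default_rng(22)
        y = 0.4 * Z["z0"] + 0.7 * Z["z1p5"] + rng.normal(0, 0.8, 700)
        one_step = gc.ContrastModel("a", 1, link="identity").fit(Z, y)
        raw = gc.residual_scores(Z, "a", 1)
        two_step = gc.two_step_fit(raw, y, link="identity")
        assert two_step["estimate"] == pytest.approx(
            one_step.reported_["estimate"], abs=1e-8
        )
        std = gc.two_step_fit(gc.standardise_scores(raw), y, link="identity")
        assert std["estimate"] == pytest.approx(
            one_step.reported_["estimate"] * raw.sd, abs=1e-8
        )

    def test_permuted_outcome_gives_null_or(self, Z900, rng):
        ors = []
        for _ in range(20):
            y = rng.permutation(Z900["outcome"].to_numpy())
            s = gc.standardise_scores(gc.residual_scores(Z900, "a", 3))
            ors.append(gc.two_step_fit(s, y)["or"])
        assert np.mean(ors) == pytest.approx(1.0, abs=0.1)

    def test_two_step_table_shape(self, Z900):
        tab = gc.two_step_table(Z900, Z900["outcome"], "b")
        assert len(tab) == 6
        assert tab["standardised"].all()


class TestScale:
    def test_reported_sd_ratio_example(self):
        sd_table, ratios = gc.score_sd_summary(
            {"Birth to 6w": 0.8, "3 to 6 m": 0.5}
        )
        assert ratios.loc["Birth to 6w", "3 to 6 m"] == pytest.approx(1.6)
        assert ratios.loc["3 to 6 m", "Birth to 6w"] == pytest.approx(0.625)

    def test_equal_sds_give_unit_ratios(self):
        _, ratios = gc.score_sd_summary({"p1": 0.4, "p2": 0.4, "p3": 0.4})
        assert np.allclose(ratios.to_numpy(), 1.0)

    def test_conditional_growth_sds_shrink_when_adjacent_correlation_tightens(self):
        """When later visits correlate ever more tightly with their
        predecessor (a Markov chain with rising adjacent correlation), later
        periods allow less population re-ordering: SD(eps) = sqrt(1 - R^2)
        falls period by period."""
        adj = np.array([0.6, 0.7, 0.8, 0.85, 0.9])
        C = np.eye(6)
        for i in range(6):
            for j in range(i + 1, 6):
                C[i, j] = C[j, i] = np.prod(adj[i:j])
        Z = gc.simulate_balanced_z(50_000, gc.CorrelationSpec(matrix=C), seed=30)
        sds = [gc.residual_scores(Z, "a", k).sd for k in range(1, 6)]
        expected = np.sqrt(1 - adj**2)  # Markov: only the previous size matters
        np.testing.assert_allclose(sds, expected, atol=0.02)
        assert (np.diff(sds) < 0).all()

    def test_density_summary_bins_and_mass(self, Z900):
        scores = [gc.residual_scores(Z900, "a", k) for k in (1, 3)]
        dens = gc.density_summary(scores, bin_width=0.25)
        for _, grp in dens.groupby("period_label"):
            width = grp["bin_right"] - grp["bin_left"]
            assert np.allclose(width, 0.25)
            assert (grp["density"] * width).sum() == pytest.approx(1.0, abs=1e-6)
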