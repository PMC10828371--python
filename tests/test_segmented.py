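"""Segmented regression: residualization, breakpoint fit, score test,
classification, scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sweetspot import (SegmentedFit, adjustment_concordance,
                       classify_relationship, fit_segmented,
                       residualize_age, score_test_slope_change,
                       sweet_spot_scan)
from sweetspot.segmented import scan_bonferroni_denominator


class TestResidualizeAge:
    def test_residuals_orthogonal_to_age(self, rng):
        age = rng.uniform(45, 85, 500)
        score = 0.01 * age + rng.normal(0, 0.05, 500)
        resid = residualize_age(score, age)
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10

    def test_zero_slope_limit_centers_scores(self, rng):
        age = rng.uniform(45, 85, 300)
        score = np.full(300, 0.4) + 0.0 * age
        resid = residualize_age(score, age)
        np.testing.assert_allclose(resid, score - score.mean(), atol=1e-12)

    def test_slope_recovery_simulation(self):
        # scores = 0.002 * age + noise: fitted slope near truth at n=5000
        slopes = []
        rng = np.random.default_rng(0)
        for _ in range(20):
            age = rng.uniform(45, 85, 5000)
            score = 0.002 * age + rng.normal(0, 0.05, 5000)
            beta = np.polyfit(age, score, 1)[0]
            slopes.append(beta)
        mc_sd = np.std(slopes)
        assert abs(np.mean(slopes) - 0.002) < 2 * mc_sd

    def test_missing_propagates(self, rng):
        age = rng.uniform(45, 85, 50)
        score = rng.normal(0, 1, 50)
        score[3] = np.nan
        resid = residualize_age(score, age)
        assert np.isnan(resid[3]) and np.isfinite(resid[4])

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            residualize_age(np.ones(10), np.full(10, 60.0))


class TestFitSegmented:
    def test_noiseless_v_recovered_exactly(self):
        x = np.arange(-3.0, 3.01, 0.1)
        y = np.abs(x - 1.0)
        fit = fit_segmented(x, y)
        assert fit.psi == pytest.approx(1.0, abs=1e-8)
        assert fit.beta1 == pytest.approx(-1.0, abs=1e-10)
        assert fit.delta == pytest.approx(2.0, abs=1e-10)
        assert fit.sse < 1e-20

    def test_sse_never_worse_than_straight_line(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 80)
            y = rng.normal(0, 1, 80)
            fit = fit_segmented(x, y)
            assert fit.sse <= fit.sse_line + 1e-9

    @given(st.floats(0.2, 5.0), st.floats(-10.0, 10.0))
    def test_breakpoint_equivariance(self, a, b):
        rng = np.random.default_rng(5)
        x = rng.uniform(-2, 4, 400)
        y = 0.1 - 0.3 * x + 0.7 * np.clip(x - 1.0, 0, None) \
            + rng.normal(0, 0.1, 400)
        f1 = fit_segmented(x, y)
        f2 = fit_segmented(a * x + b, y)
        assert f2.psi == pytest.approx(a * f1.psi + b,
                                       abs=1e-4 * max(1, abs(a)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_segmented(np.arange(5.0), np.arange(5.0))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_segmented(np.ones(30), np.random.default_rng(0).normal(
                0, 1, 30))

    def test_right_slope_property(self):
        x = np.arange(-3.0, 3.01, 0.1)
        fit = fit_segmented(x, np.abs(x))
        assert fit.right_slope == pytest.approx(fit.beta1 + fit.delta)


class TestScoreTest:
    def test_overwhelming_signal(self, rng):
        x = rng.uniform(-3, 3, 1000)
        y = -0.5 * x + 1.2 * np.clip(x, 0, None) + rng.normal(0, 0.1, 1000)
        assert score_test_slope_change(x, y) < 1e-6

    def test_invariant_under_affine_null_terms(self, rng):
        x = rng.uniform(-3, 3, 300)
        y = rng.normal(0, 1, 300)
        p0 = score_test_slope_change(x, y)
        p1 = score_test_slope_change(x, y + 3.7 - 2.2 * x)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_null_calibration_quick(self):
        rng = np.random.default_rng(1)
        rej = np.mean([
            score_test_slope_change(rng.standard_normal(200),
                                    rng.standard_normal(200)) < 0.05
            for _ in range(400)])
        assert 0.02 < rej < 0.08


class TestClassify:
    def _fit(self, beta1, delta, se=0.01, psi=1.0):
        right = beta1 + delta
        return SegmentedFit(
            beta0=0.0, beta1=beta1, delta=delta, psi=psi,
            se_beta1=se, se_right=se, se_psi=0.1,
            ci_beta1=(beta1 - 2 * se, beta1 + 2 * se),
            ci_right=(right - 2 * se, right + 2 * se),
            ci_psi=(psi - 0.2, psi + 0.2), n=100, sse=1.0, sse_line=2.0,
            converged=True, iterations=3, method="iterative")

    def test_all_three_criteria_give_sweet_spot(self):
        out = classify_relationship(self._fit(-0.1, 0.25), 0.002)
        assert out["relationship"] == "nonmonotonic_sweet_spot"
        assert out["psi"] == pytest.approx(1.0)

    def test_same_sign_slopes_never_sweet_spot(self):
        out = classify_relationship(self._fit(0.1, 0.2), 1e-10)
        assert out["relationship"] == "increasing"
        out = classify_relationship(self._fit(-0.3, 0.1), 1e-10)
        assert out["relationship"] == "decreasing"

    def test_right_slope_ci_containing_zero_blocks_sweet_spot(self):
        fit = self._fit(-0.1, 0.105, se=0.01)  # right slope 0.005 < 2 se
        out = classify_relationship(fit, 0.001)
        assert out["relationship"] == "nonmonotonic_nonsignificant"

    def test_nonsignificant_p_blocks_sweet_spot(self):
        out = classify_relationship(self._fit(-0.1, 0.25), 0.2)
        assert out["relationship"] == "nonmonotonic_nonsignificant"

    def test_straight_line_fallback(self):
        out = classify_relationship(None, np.nan, line_slope_ci=(0.01, 0.05))
        assert out["relationship"] == "increasing"
        out = classify_relationship(None, np.nan, line_slope_ci=(-0.01, 0.05))
        assert out["relationship"] == "flat"


class TestScan:
    def test_empty_selection_gives_empty_table(self, demo_cohort,
                                               demo_scores):
        _, table, _ = demo_cohort
        scores, _ = demo_scores
        out = sweet_spot_scan(table, scores, [])
        assert len(out) == 0

    def test_bonferroni_denominator_fixed_product(self):
        assert scan_bonferroni_denominator(142) == 1420
        assert scan_bonferroni_denominator(62) == 620

    def test_recorded_m_matches_plan(self, demo_cohort, demo_scores):
        _, table, _ = demo_cohort
        scores, _ = demo_scores
        out = sweet_spot_scan(table, scores, ["sweet1", "null1"])
        assert (out["m_tests"] == scan_bonferroni_denominator(2)).all()

    def test_row_filter_restricts_rows(self, demo_cohort, demo_scores):
        _, table, _ = demo_cohort
        scores, _ = demo_scores
        full = sweet_spot_scan(table, scores, ["sweet1"],
                               instruments=("I",))
        young = sweet_spot_scan(table, scores, ["sweet1"],
                                instruments=("I",), row_filter="age < 65")
        assert (young["n"] < full["n"]).all()

    def test_covariate_adjustment_keeps_planted_breakpoint(self, demo_cohort,
                                                           demo_scores):
        cfg, table, registry = demo_cohort
        scores, _ = demo_scores
        unadj = sweet_spot_scan(table, scores, ["sweet1", "sweet2"],
                                instruments=("I", "V"))
        adj = sweet_spot_scan(table, scores, ["sweet1", "sweet2"],
                              instruments=("I", "V"),
                              covariates=["smoking", "income"])
        r2 = adjustment_concordance(unadj, adj)
        # covariates are independent noise, so breakpoints barely move
        assert r2 > 0.99


def test_scan_output_schema(demo_cohort, demo_scores):
    _, table, _ = demo_cohort
    scores, _ = demo_scores
    out = sweet_spot_scan(table, scores, ["sweet1"], instruments=("I",))
    assert set(["phenotype", "instrument", "sex", "relationship", "psi",
                "psi_lo", "psi_hi", "p_score_raw", "p_score_bonferroni",
                "n", "converged", "method"]).issubset(out.columns)
    assert sorted(out["sex"].unique()) == ["F", "M"]
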