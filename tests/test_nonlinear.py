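import numpy as np
import pandas as pd
import pytest

import proteomr as pm
from conftest import simple_iv_cohort


def _est_frame(lows, highs, x_means, laces, ses, den=1.0):
    k = len(laces)
    return pd.DataFrame({
        "stratum": np.arange(1, k + 1), "low": lows, "high": highs,
        "x_mean": x_means, "n": np.full(k, 100),
        "beta_num": np.asarray(laces) * den, "se_num": np.asarray(ses) * den,
        "beta_den": den, "se_den": 0.01 * den,
        "lace": laces, "se_lace": ses})


class TestGsFree:
    def test_mean_and_orthogonality(self):
        rng = np.random.default_rng(20)
        cohort, g, _ = simple_iv_cohort(rng, n=1000)
        gf = pm.gs_free_residuals(cohort, g)
        assert gf.mean() == pytest.approx(cohort["bmi"].mean(), abs=1e-10)
        assert abs(np.corrcoef(gf, g)[0, 1]) < 1e-10

    def test_uncorrelated_score_returns_bmi(self):
        rng = np.random.default_rng(21)
        cohort, _, _ = simple_iv_cohort(rng, n=500)
        bmi = cohort["bmi"].to_numpy()
        # construct a score exactly orthogonal to centered BMI
        g0 = rng.normal(0, 1, 500)
        bc = bmi - bmi.mean()
        g0 = g0 - bc * (g0 @ bc) / (bc @ bc)
        gf = pm.gs_free_residuals(cohort, g0)
        np.testing.assert_allclose(gf, bmi, atol=1e-9)


class TestLace:
    def test_linear_truth_constant_lace(self):
        """Per-stratum ratio estimates all center on the single causal
        slope when the true effect is linear."""
        rng = np.random.default_rng(22)
        all_lace = []
        for _ in range(30):
            cohort, g, y = simple_iv_cohort(rng, n=4000, beta=0.4)
            gf = pm.gs_free_residuals(cohort, g)
            est = pm.lace_estimates(cohort, g, y, gf, covariates=None)
            all_lace.append(est["lace"].to_numpy())
        mean_lace = np.mean(all_lace, axis=0) * 3.3   # per kg/m2 -> per SD
        np.testing.assert_allclose(mean_lace, 0.4, atol=0.06)

    def test_null_protein_centers_on_zero(self):
        rng = np.random.default_rng(23)
        cohort, g, _ = simple_iv_cohort(rng, n=4000)
        y = rng.normal(0, 1, 4000)
        gf = pm.gs_free_residuals(cohort, g)
        est = pm.lace_estimates(cohort, g, y, gf, covariates=None)
        assert (np.abs(est["lace"]) < 4 * est["se_lace"]).all()

    def test_shared_denominator_and_sizes(self):
        rng = np.random.default_rng(24)
        cohort, g, y = simple_iv_cohort(rng, n=1003)
        gf = pm.gs_free_residuals(cohort, g)
        est = pm.lace_estimates(cohort, g, y, gf, covariates=None)
        assert est["beta_den"].nunique() == 1
        assert est["n"].max() - est["n"].min() <= 1

    def test_second_order_se_negligible_for_strong_instrument(self):
        rng = np.random.default_rng(25)
        cohort, g, y = simple_iv_cohort(rng, n=4000, beta=0.3)
        gf = pm.gs_free_residuals(cohort, g)
        e1 = pm.lace_estimates(cohort, g, y, gf, covariates=None)
        e2 = pm.lace_estimates(cohort, g, y, gf, covariates=None,
                               second_order=True)
        assert (e2["se_lace"] >= e1["se_lace"]).all()
        np.testing.assert_allclose(e2["se_lace"], e1["se_lace"], rtol=0.2)

    def test_ivw_pooled_lace_matches_tsls(self):
        """Pooling the stratum estimates recovers the one-sample 2SLS
        estimate under linear truth (within Monte-Carlo error)."""
        rng = np.random.default_rng(26)
        diffs = []
        for _ in range(20):
            cohort, g, y = simple_iv_cohort(rng, n=4000, beta=0.35)
            gf = pm.gs_free_residuals(cohort, g)
            est = pm.lace_estimates(cohort, g, y, gf, covariates=None)
            w = 1.0 / est["se_lace"] ** 2
            pooled = np.sum(w * est["lace"]) / np.sum(w)
            diag = pm.stage1_fit(cohort, g, covariates=None)
            tsls = pm.tsls_protein(cohort, diag, pd.Series(y),
                                   covariates=None,
                                   bmi_increment=1.0).loc[0, "beta"]
            diffs.append(pooled - tsls)
        assert abs(np.mean(diffs)) < 0.02


class TestPiecewise:
    def test_equal_slopes_collapse_to_line(self):
        est = _est_frame([20, 24], [24, 28], [22, 26], [0.2, 0.2],
                         [0.05, 0.05])
        curve = pm.build_piecewise(est, anchor_bmi=23.9)
        x = np.linspace(20, 28, 50)
        np.testing.assert_allclose(curve(x), 0.2 * (x - 23.9), atol=1e-12)

    def test_hand_assembled_polyline(self):
        # slopes (0.1, 0.3), breakpoints (20, 24, 28), anchor 23.9:
        # rises 0.4 then 1.2; value at anchor pre-shift = 0.1*3.9 = 0.39
        est = _est_frame([20, 24], [24, 28], [22, 26], [0.1, 0.3],
                         [0.05, 0.05])
        curve = pm.build_piecewise(est, anchor_bmi=23.9)
        np.testing.assert_allclose(curve.breakpoints, [20, 24, 28])
        np.testing.assert_allclose(curve.values,
                                   [0 - 0.39, 0.4 - 0.39, 1.6 - 0.39],
                                   atol=1e-12)

    def test_anchor_constraint_exact(self):
        est = _est_frame([18, 23, 26], [23, 26, 32], [20, 24.5, 29],
                         [0.1, -0.2, 0.4], [0.05] * 3)
        curve = pm.build_piecewise(est, anchor_bmi=24.3)
        assert curve(np.array([24.3]))[0] == 0.0

    def test_continuity_between_segments(self):
        est = _est_frame([18, 23, 26], [23, 26, 32], [20, 24.5, 29],
                         [0.5, -0.8, 1.2], [0.05] * 3)
        curve = pm.build_piecewise(est, anchor_bmi=24.0)
        eps = 1e-9
        for b in curve.breakpoints[1:-1]:
            left = curve(np.array([b - eps]))[0]
            right = curve(np.array([b + eps]))[0]
            assert left == pytest.approx(right, abs=1e-6)

    def test_non_contiguous_ranges_error(self):
        est = _est_frame([20, 26], [23, 30], [21, 28], [0.1, 0.2],
                         [0.05, 0.05])
        est.loc[1, "low"] = 19.0     # overlaps the first stratum
        with pytest.raises(ValueError, match="contiguous"):
            pm.build_piecewise(est, anchor_bmi=23.9)


class TestBootstrap:
    def test_same_seed_identical_bands(self):
        rng = np.random.default_rng(27)
        cohort, g, y = simple_iv_cohort(rng, n=1500, beta=0.3)
        gf = pm.gs_free_residuals(cohort, g)
        c1 = pm.bootstrap_bands(cohort, g, y, gf, B=120, seed=9,
                                covariates=None)
        c2 = pm.bootstrap_bands(cohort, g, y, gf, B=120, seed=9,
                                covariates=None)
        np.testing.assert_array_equal(c1.ci_lower, c2.ci_lower)
        np.testing.assert_array_equal(c1.ci_upper, c2.ci_upper)

    def test_bands_contain_point_curve(self):
        rng = np.random.default_rng(28)
        cohort, g, y = simple_iv_cohort(rng, n=1500, beta=0.3)
        gf = pm.gs_free_residuals(cohort, g)
        c = pm.bootstrap_bands(cohort, g, y, gf, B=150, seed=1,
                               covariates=None)
        assert (c.ci_lower <= c.values + 1e-12).all()
        assert (c.ci_upper >= c.values - 1e-12).all()

    def test_linear_truth_band_coverage(self):
        """The 95% bands cover the true causal line at each breakpoint at
        close to nominal (pointwise) rate under linear truth."""
        rng = np.random.default_rng(29)
        covered = []
        for _ in range(60):
            cohort, g, y = simple_iv_cohort(rng, n=2000, beta=0.35)
            sd = cohort["bmi"].std()
            gf = pm.gs_free_residuals(cohort, g)
            c = pm.bootstrap_bands(cohort, g, y, gf, B=300,
                                   seed=int(rng.integers(2 ** 31)),
                                   covariates=None)
            true_vals = 0.35 / sd * (c.breakpoints - c.anchor)
            covered.append((c.ci_lower <= true_vals)
                           & (true_vals <= c.ci_upper))
        per_bp = np.mean(covered, axis=0)
        assert 0.90 <= per_bp.mean() <= 0.99
        assert per_bp.min() >= 0.85

    def test_band_halfwidth_stabilizes_with_B(self):
        """Percentile band half-widths change little once B is large."""
        rng = np.random.default_rng(129)
        cohort, g, y = simple_iv_cohort(rng, n=2000, beta=0.35)
        gf = pm.gs_free_residuals(cohort, g)
        c1 = pm.bootstrap_bands(cohort, g, y, gf, B=1000, seed=4,
                                covariates=None)
        c2 = pm.bootstrap_bands(cohort, g, y, gf, B=2000, seed=5,
                                covariates=None)
        w1 = c1.ci_upper - c1.ci_lower
        w2 = c2.ci_upper - c2.ci_lower
        rel = np.abs(w1[1:] - w2[1:]) / w2[1:]   # anchor-adjacent widths >0
        assert np.median(rel) < 0.08

    def test_b_too_small_errors(self):
        rng = np.random.default_rng(30)
        cohort, g, y = simple_iv_cohort(rng, n=500)
        gf = pm.gs_free_residuals(cohort, g)
        with pytest.raises(ValueError, match="at least 100"):
            pm.bootstrap_bands(cohort, g, y, gf, B=50)


class TestTrendQuad:
    def test_identical_lace_gives_null_trend(self):
        est = _est_frame([18, 22, 26], [22, 26, 30], [20, 24, 28],
                         [0.3, 0.3, 0.3], [0.05] * 3)
        x2t, pt, x2q, pq = pm.trend_quad_tests(est)
        assert x2t == pytest.approx(0.0, abs=1e-20)
        assert pt == pytest.approx(1.0)

    def test_linear_increase_with_tiny_se(self):
        est = _est_frame([18, 22, 26], [22, 26, 30], [20, 24, 28],
                         [0.1, 0.2, 0.3], [1e-4] * 3)
        x2t, pt, x2q, pq = pm.trend_quad_tests(est)
        assert pt < 1e-10
        assert pq > 0.5            # no curvature in a straight line

    def test_quadratic_pattern_detected(self):
        est = _est_frame([18, 22, 26], [22, 26, 30], [20, 24, 28],
                         [0.3, 0.1, 0.3], [1e-4] * 3)
        _, _, x2q, pq = pm.trend_quad_tests(est)
        assert pq < 1e-10

    def test_two_strata_omit_quadratic(self):
        est = _est_frame([18, 24], [24, 30], [21, 27], [0.1, 0.3],
                         [0.05, 0.05])
        x2t, pt, x2q, pq = pm.trend_quad_tests(est)
        assert x2q is None and pq is None
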