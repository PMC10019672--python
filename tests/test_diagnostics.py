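"""TOW-stratified diagnostics, CV-constancy check, residual QQ."""

import numpy as np
import pytest

import growthcustom as gc
from growthcustom.diagnostics import (
    bin_by_predicted_tow,
    cv_constancy_table,
    empirical_percentile,
    percentile_agreement_table,
    residual_qq,
)
from growthcustom.published import nichd_gardosi_results
from growthcustom.simulate import true_moments


def constant_cv_cohort(n, seed, cv=0.129):
    """Deliveries whose birthweight is N(TOW, (cv*TOW)^2) at the published
    constant-CV chart — data simulated from the Gardosi engine's own model."""
    rng = np.random.default_rng(seed)
    recs = gc.generate_cohort(gc.SyntheticConfig(n=n, seed=seed))
    chart = nichd_gardosi_results()
    X = gc.design_matrix(recs)
    tow = np.asarray(chart.predict_tow(X))
    for r, t in zip(recs, tow):
        r.birthweight = float(max(rng.normal(t, cv * t), 250.0))
    return recs, chart


class TestBinning:
    def test_partition_sums_to_cohort(self, medium_cohort, gardosi_chart):
        bins = bin_by_predicted_tow(medium_cohort, gardosi_chart, k=8)
        assert sum(b.n for b in bins) == len(medium_cohort)
        assert len(bins) == 8

    def test_equal_length_boundaries(self, medium_cohort, gardosi_chart):
        bins = bin_by_predicted_tow(medium_cohort, gardosi_chart, k=8)
        widths = [b.hi - b.lo for b in bins]
        assert np.allclose(widths, widths[0])

    def test_uniform_prediction_boundary_arithmetic(self):
        # stub chart mapping records onto a known uniform prediction grid
        class UniformChart:
            convention = gc.CenteringConvention()
            cv = 0.1

            def predict_tow(self, X):
                return np.linspace(3000, 3800, len(X))

            def percentile_at_tow(self, tow, spec):
                return np.asarray(tow, float)

        recs = gc.generate_cohort(gc.SyntheticConfig(n=41, seed=1))
        bins = bin_by_predicted_tow(recs, UniformChart(), k=8)
        edges = [b.lo for b in bins] + [bins[-1].hi]
        assert np.allclose(edges, np.arange(3000, 3801, 100))

    def test_membership_matches_brute_force(self, gardosi_chart):
        recs = gc.generate_cohort(gc.SyntheticConfig(n=16, seed=8))
        bins = bin_by_predicted_tow(recs, gardosi_chart, k=4)
        X = gc.design_matrix(recs)
        pred = np.asarray(gardosi_chart.predict_tow(X))
        for value in pred:
            assert sum(b.contains(value) for b in bins) == 1
        for b in bins:
            assert b.n == sum(b.contains(v) for v in pred)

    def test_degenerate_identical_predictions_rejected(self):
        class FlatChart:
            convention = gc.CenteringConvention()

            def predict_tow(self, X):
                return np.full(len(X), 3400.0)

        recs = gc.generate_cohort(gc.SyntheticConfig(n=20, seed=2))
        with pytest.raises(ValueError, match="zero-width"):
            bin_by_predicted_tow(recs, FlatChart(), k=4)


class TestEmpiricalPercentile:
    def test_small_examples(self):
        assert empirical_percentile([1, 2, 3, 4, 5], 0.5) == 3
        assert empirical_percentile([7.5], 0.9) == 7.5
        with pytest.raises(ValueError):
            empirical_percentile([], 0.5)

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(size=100)
        # type-7: index (n-1)*q into the sorted sample, linear interpolation
        srt = np.sort(vals)
        pos = 99 * 0.9
        lo, frac = int(pos), pos - int(pos)
        expected = srt[lo] * (1 - frac) + srt[lo + 1] * frac
        assert empirical_percentile(vals, 0.9) == pytest.approx(expected, rel=1e-12)


class TestCVConstancy:
    def test_constant_cv_truth_recovers_slope(self):
        recs, chart = constant_cv_cohort(6000, seed=5)
        fit = gc.fit_mean_model(recs)
        bins = bin_by_predicted_tow(recs, fit, k=8)
        out = cv_constancy_table(bins, fit.cv)
        assert out["slope_through_origin"] == pytest.approx(0.129, abs=0.02)
        usable = out["table"].dropna(subset=["deviation"])
        big = usable[usable.n >= 100]
        assert np.all(np.abs(big.deviation) < 60)

    def test_mean_independent_sigma_flagged_flat(self):
        rng = np.random.default_rng(23)
        recs = gc.generate_cohort(gc.SyntheticConfig(n=6000, seed=23))
        chart = nichd_gardosi_results()
        X = gc.design_matrix(recs)
        tow = np.asarray(chart.predict_tow(X))
        for r, t in zip(recs, tow):
            r.birthweight = float(rng.normal(t, 350.0))    # SD free of mean
        fit = gc.fit_mean_model(recs)
        bins = bin_by_predicted_tow(recs, fit, k=8)
        out = cv_constancy_table(bins, fit.cv)
        # regression of SD on bin mean should be near flat, far from the CV
        assert abs(out["slope"]) < 0.05

    def test_small_bins_kept_in_table_excluded_from_fit(self, gardosi_chart):
        recs = gc.generate_cohort(gc.SyntheticConfig(n=60, seed=3))
        bins = bin_by_predicted_tow(recs, gardosi_chart, k=8)
        out = cv_constancy_table(bins, 0.129)
        assert len(out["table"]) == 8
        tiny = [b for b in bins if b.n < 2]
        for b in tiny:
            assert b.sd_bw is None


class TestPercentileAgreement:
    def test_self_consistency_on_own_model(self):
        recs, _ = constant_cv_cohort(6000, seed=14)
        fit = gc.fit_mean_model(recs)
        bins = bin_by_predicted_tow(recs, fit, k=8)
        table = percentile_agreement_table(bins, qs=(0.05, 0.95))
        big = table[table.n >= 300]
        assert np.abs(big.diff_05).mean() < 40
        assert np.abs(big.diff_95).mean() < 40

    def test_heavy_right_tail_underestimates_p95(self):
        rng = np.random.default_rng(6)
        recs = gc.generate_cohort(gc.SyntheticConfig(n=6000, seed=6))
        chart = nichd_gardosi_results()
        X = gc.design_matrix(recs)
        tow = np.asarray(chart.predict_tow(X))
        noise = rng.lognormal(mean=0.0, sigma=0.5, size=len(recs))
        for r, t, z in zip(recs, tow, noise):
            r.birthweight = float(t + 400 * (z - np.exp(0.125)))
        fit = gc.fit_mean_model(recs)
        bins = bin_by_predicted_tow(recs, fit, k=8)
        table = percentile_agreement_table(bins, qs=(0.05, 0.95))
        big = table[table.n >= 300]
        # positive difference = empirical above model = model under-estimates
        assert big.diff_95.mean() > 0
        # and the symmetric-normal model over-estimates the depressed 5th
        assert big.diff_05.mean() > 0

    def test_gardosi_chart_on_heteroscedastic_truth_shows_disagreement(self):
        recs = gc.generate_cohort(gc.SyntheticConfig(
            n=8000, seed=44, gamma={"weight": 0.06, "height": 0.03}))
        fit = gc.fit_mean_model(recs)
        bins = bin_by_predicted_tow(recs, fit, k=8)
        table = percentile_agreement_table(bins, qs=(0.05, 0.95))
        big = table[table.n >= 200]
        assert np.abs(np.r_[big.diff_05, big.diff_95]).max() > 50


class TestResidualQQ:
    def test_normal_residuals_line_near_identity(self, medium_cohort):
        fit = gc.fit_heteroscedastic(medium_cohort)
        qq = residual_qq(fit)
        assert qq["slope"] == pytest.approx(1.0, abs=0.08)
        assert qq["intercept"] == pytest.approx(0.0, abs=0.05)
        assert qq["shapiro_w"] > 0.98

    def test_t3_tails_detected(self):
        rng = np.random.default_rng(2)
        recs = gc.generate_cohort(gc.SyntheticConfig(n=4000, seed=2))
        cfg = gc.SyntheticConfig(n=4000, seed=2)
        mean, sigma = true_moments(recs, cfg)
        for r, m, s in zip(recs, mean, sigma):
            r.birthweight = float(m + s * rng.standard_t(3) / np.sqrt(3))
        fit_t = gc.fit_heteroscedastic(recs)
        qq_t = residual_qq(fit_t)
        base = residual_qq(gc.fit_heteroscedastic(
            gc.generate_cohort(cfg)))
        assert qq_t["max_abs_deviation"] > base["max_abs_deviation"]
        assert qq_t["shapiro_w"] < base["shapiro_w"]

    def test_constant_residuals_degenerate(self):
        recs = gc.generate_cohort(gc.SyntheticConfig(n=100, seed=1))
        chart = nichd_gardosi_results()
        X = gc.design_matrix(recs)
        tow = np.asarray(chart.predict_tow(X))
        for r, t in zip(recs, tow):
            r.birthweight = float(t + 100.0)   # identical residuals
        qq = residual_qq(chart, recs)
        assert qq["degenerate"]
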