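"""SGA/LGA classification, 2x2 metrics, c-statistic, logistic fit."""

import numpy as np
import pandas as pd
import pytest

import growthcustom as gc
from growthcustom.screening import (
    PopulationReference,
    SeparationError,
    c_statistic,
    classify,
    classify_population,
    composite_morbidity,
    confusion_from_rates,
    confusion_metrics,
    fit_logistic,
)


class TestClassify:
    def test_exactly_at_cut_is_not_flagged(self, hetero_chart):
        rec = gc.PregnancyRecord(163, 64, 0, "NH-White", "male", 280, 3500)
        X = gc.design_matrix([rec])
        cut10 = hetero_chart.percentile(X.iloc[0], 0.10, round_grams=False)
        rec.birthweight = float(cut10)
        out = classify([rec], hetero_chart)
        assert not out.sga.iloc[0]
        rec.birthweight = float(cut10) - 1e-6
        assert classify([rec], hetero_chart).sga.iloc[0]

    def test_calibration_under_own_truth(self, medium_cohort, hetero_chart):
        # classify with the true generating chart: ~10% SGA within 3 binomial SD
        out = classify(medium_cohort, hetero_chart)
        n = len(medium_cohort)
        sd = np.sqrt(0.1 * 0.9 / n)
        assert abs(out.sga.mean() - 0.10) < 3 * sd + 0.005
        assert abs(out.lga.mean() - 0.10) < 3 * sd + 0.005

    def test_never_both_sga_and_lga(self, medium_cohort, gardosi_chart):
        out = classify(medium_cohort, gardosi_chart)
        assert not (out.sga & out.lga).any()

    def test_hetero_flags_more_sga_than_gardosi(self, medium_cohort,
                                                gardosi_chart, hetero_chart):
        # the heteroscedastic 10th-percentile cut is higher (published worked
        # rows: 2994 vs 2878), so it must flag at least as many deliveries
        g = classify(medium_cohort, gardosi_chart)
        h = classify(medium_cohort, hetero_chart)
        assert h.sga.sum() > g.sga.sum()

    def test_population_reference_lookup(self):
        table = {(40, "male", 0.10): 3000.0, (40, "male", 0.90): 4000.0}
        ref = PopulationReference(table)
        recs = [gc.PregnancyRecord(163, 64, 0, "NH-White", "male", 280, bw)
                for bw in (2900, 3500, 4100)]
        out = classify_population(recs, ref)
        assert list(out.sga) == [True, False, False]
        assert list(out.lga) == [False, False, True]
        # missing table entry -> excluded with log
        recs.append(gc.PregnancyRecord(163, 64, 0, "NH-White", "female", 280, 3000))
        out = classify_population(recs, ref)
        assert len(out) == 3 and len(out.attrs["excluded"]) == 1


class TestConfusionMetrics:
    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(0)
        flags = rng.random(20) < 0.4
        outcome = rng.random(20) < 0.3
        m = confusion_metrics(flags, outcome)
        tp = sum(f and o for f, o in zip(flags, outcome))
        fp = sum(f and not o for f, o in zip(flags, outcome))
        fn = sum(o and not f for f, o in zip(flags, outcome))
        tn = 20 - tp - fp - fn
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.ppv == pytest.approx(tp / (tp + fp))
        assert m.npv == pytest.approx(tn / (tn + fn))
        assert m.odds_ratio == pytest.approx((tp * tn) / (fp * fn))
        assert m.n == 20

    def test_ppv_npv_recompute_from_cells(self, medium_cohort, gardosi_chart):
        gc.generate_morbidity(medium_cohort, gc.SyntheticConfig(n=3000, seed=7))
        out = classify(medium_cohort, gardosi_chart)
        m = confusion_metrics(out.sga, [r.morbidity_sga for r in medium_cohort])
        assert m.ppv == pytest.approx(m.tp / (m.tp + m.fp), abs=1e-12)
        assert m.npv == pytest.approx(m.tn / (m.tn + m.fn), abs=1e-12)

    def test_published_or_identities(self):
        assert confusion_from_rates(0.132, 0.9309).odds_ratio == \
            pytest.approx(2.05, abs=0.005)
        assert confusion_from_rates(0.149, 0.8985).odds_ratio == \
            pytest.approx(1.55, abs=0.005)

    def test_perfect_classifier_continuity_corrected(self):
        with pytest.warns(UserWarning, match="continuity"):
            m = confusion_metrics([True] * 5 + [False] * 5,
                                  [True] * 5 + [False] * 5)
        assert m.continuity_corrected
        assert np.isfinite(m.odds_ratio)

    def test_cells_sum_and_proportions_bounded(self):
        m = confusion_from_rates(0.2, 0.8, 100, 900)
        assert m.n == 1000
        for v in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert 0 <= v <= 1


class TestCStatistic:
    def test_binary_flag_identity(self):
        rng = np.random.default_rng(5)
        flags = rng.random(500) < 0.2
        outcome = rng.random(500) < 0.1
        m = confusion_metrics(flags, outcome)
        assert c_statistic(flags.astype(float), outcome) == \
            pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)

    def test_published_binary_example(self):
        # sens 14.9%, spec 89.85% -> c = 0.52 at table precision
        m = confusion_from_rates(0.149, 0.8985)
        assert round(m.c_statistic, 2) == 0.52

    def test_independent_score_near_half(self):
        rng = np.random.default_rng(9)
        score = rng.normal(size=20000)
        outcome = rng.random(20000) < 0.3
        assert c_statistic(score, outcome) == pytest.approx(0.5, abs=0.02)

    def test_matches_all_pairs_brute_force(self):
        score = np.array([0.1, 0.9, 0.4, 0.4, 0.7, 0.2, 0.8, 0.3])
        outcome = np.array([0, 1, 0, 1, 1, 0, 1, 0], bool)
        wins = ties = 0
        for sp in score[outcome]:
            for sn in score[~outcome]:
                wins += sp > sn
                ties += sp == sn
        expected = (wins + 0.5 * ties) / (outcome.sum() * (~outcome).sum())
        assert c_statistic(score, outcome) == pytest.approx(expected, abs=1e-12)

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([1.0, 2.0], [True, True])


class TestLogistic:
    def test_intercept_only_recovers_logit_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        res = fit_logistic(y, np.ones((100, 1)))
        assert res.params.iloc[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_binary_covariate_equals_2x2_log_or(self):
        rng = np.random.default_rng(3)
        x = (rng.random(400) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-(-2.0 + 0.9 * x)))
        y = (rng.random(400) < p).astype(float)
        X = pd.DataFrame({"intercept": np.ones(400), "x": x})
        res = fit_logistic(y, X)
        a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1)); d = np.sum((x == 0) & (y == 0))
        assert res.params["x"] == pytest.approx(np.log((a * d) / (b * c)), abs=1e-6)

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        y = (rng.random(5000) < p).astype(float)
        X = pd.DataFrame({"intercept": np.ones(5000), "x": x})
        res = fit_logistic(y, X)
        assert res.params["x"] == pytest.approx(0.8, abs=4 * res.bse["x"])

    def test_separation_names_column(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = pd.DataFrame({"intercept": np.ones(40), "sep_col": x})
        with pytest.raises(SeparationError, match="sep_col"):
            fit_logistic(y, X)


class TestCompositeMorbidity:
    def test_all_false_is_false(self):
        flags = pd.DataFrame({"pneumonia": [False, False], "sepsis": [False, False]})
        assert not composite_morbidity(flags, "SGA").any()

    def test_birth_injury_lga_only(self):
        flags = pd.DataFrame({"birth_injury": [True]})
        assert composite_morbidity(flags, "LGA").iloc[0]
        assert not composite_morbidity(flags, "SGA").iloc[0]

    def test_sga_only_components_respected(self):
        flags = pd.DataFrame({"pvl": [True], "rop": [False]})
        assert composite_morbidity(flags, "SGA").iloc[0]
        assert not composite_morbidity(flags, "LGA").iloc[0]

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(1)
        cols = ["pneumonia", "rds", "pvl", "birth_injury", "hypoglycemia"]
        flags = pd.DataFrame(rng.random((30, 5)) < 0.2, columns=cols)
        sga_cols = ["pneumonia", "rds", "pvl", "hypoglycemia"]
        lga_cols = ["pneumonia", "rds", "birth_injury", "hypoglycemia"]
        assert (composite_morbidity(flags, "SGA")
                == flags[sga_cols].any(axis=1)).all()
        assert (composite_morbidity(flags, "LGA")
                == flags[lga_cols].any(axis=1)).all()

    def test_missing_components_logged(self):
        flags = pd.DataFrame({"pneumonia": [True]})
        out = composite_morbidity(flags, "SGA")
        assert "sepsis" in out.attrs["missing"]
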