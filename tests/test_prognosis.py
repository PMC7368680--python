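"""Prediction formulas, recovery dichotomy, ROC/AUC, regression utilities."""

import numpy as np
import pandas as pd
import pytest

import asfm3d as a
from asfm3d.prognosis import HIGHER_PREDICTS_POOR, LOWER_PREDICTS_POOR


class TestPredictionFormulas:
    def test_month1_intercept(self):
        assert a.predict_month1(0.0).raw == pytest.approx(132.112)

    def test_month1_full_degeneration(self):
        assert a.predict_month1(100.0).raw == pytest.approx(62.212)

    def test_month1_strictly_decreasing(self):
        xs = np.linspace(0, 100, 11)
        ys = [a.predict_month1(x).raw for x in xs]
        assert all(y0 > y1 for y0, y1 in zip(ys, ys[1:]))

    def test_month2_intercept(self):
        assert a.predict_month2(0.0, 0.0).raw == pytest.approx(13.457)

    def test_month2_saturated_inputs(self):
        p = a.predict_month2(100.0, 100.0)
        assert p.raw == pytest.approx(134.157)
        assert p.clamped == 100.0

    def test_month2_monotone_nondecreasing(self):
        base = a.predict_month2(50.0, 50.0).raw
        assert a.predict_month2(60.0, 50.0).raw > base
        assert a.predict_month2(50.0, 60.0).raw > base

    def test_formulas_are_affine(self, rng):
        """f(mean of inputs) equals mean of outputs."""
        xs = rng.uniform(0, 100, 20)
        assert a.predict_month1(xs.mean()).raw == pytest.approx(
            np.mean([a.predict_month1(x).raw for x in xs])
        )
        x1, x2 = rng.uniform(0, 100, 20), rng.uniform(0, 100, 20)
        assert a.predict_month2(x1.mean(), x2.mean()).raw == pytest.approx(
            np.mean([a.predict_month2(u, v).raw for u, v in zip(x1, x2)])
        )

    @pytest.mark.parametrize("bad", [-1.0, 100.5])
    def test_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(a.ValidationError):
            a.predict_month1(bad)
        with pytest.raises(a.ValidationError):
            a.predict_month2(bad, 50.0)


class TestRecoveryClassification:
    def _rec(self, **kw):
        return a.ClinicalRecord(patient_id="p", **kw)

    @pytest.mark.parametrize("sfgs,expected", [(70.0, "good"), (69.0, "poor"), (100.0, "good")])
    def test_sfgs_threshold(self, sfgs, expected):
        assert a.classify_recovery(self._rec(sfgs=sfgs))["sfgs"] == expected

    @pytest.mark.parametrize(
        "grade,expected",
        [(a.HBGrade.I, "good"), (a.HBGrade.II, "good"), (a.HBGrade.III, "poor"), (a.HBGrade.VI, "poor")],
    )
    def test_hbgs_threshold(self, grade, expected):
        assert a.classify_recovery(self._rec(hbgs=grade))["hbgs"] == expected

    def test_no_outcome_errors(self):
        with pytest.raises(a.ValidationError):
            a.classify_recovery(self._rec())

    def test_constructed_cohort_counts_are_exact(self):
        """25 of 37 records built with final SFGS ≥ 70 classify as good."""
        records = [self._rec(sfgs=float(70 + i % 30)) for i in range(25)]
        records += [self._rec(sfgs=float(10 + i % 59)) for i in range(12)]
        rate = a.recovery_rate_percent(records, "sfgs")
        assert rate == pytest.approx(100.0 * 25 / 37)


def _mann_whitney_auc(values, positive, direction):
    """Concordant-pair counting oracle (ties count half)."""
    pos = [v for v, p in zip(values, positive) if p]
    neg = [v for v, p in zip(values, positive) if not p]
    total = 0.0
    for vp in pos:
        for vn in neg:
            better = vp < vn if direction == LOWER_PREDICTS_POOR else vp > vn
            total += 1.0 if better else 0.5 if vp == vn else 0.0
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        pairs = [(10.0, "poor")] * 4 + [(90.0, "good")] * 5
        r = a.roc(pairs, LOWER_PREDICTS_POOR, n_boot=50, seed=1)
        assert r.auc == pytest.approx(1.0)

    def test_all_equal_scores_auc_half(self):
        pairs = [(50.0, "poor")] * 4 + [(50.0, "good")] * 4
        r = a.roc(pairs, LOWER_PREDICTS_POOR, n_boot=50, seed=1)
        assert r.auc == pytest.approx(0.5)

    def test_six_point_toy_matches_pair_counting(self):
        pairs = [(20.0, "poor"), (35.0, "poor"), (35.0, "good"),
                 (50.0, "good"), (28.0, "poor"), (60.0, "good")]
        r = a.roc(pairs, LOWER_PREDICTS_POOR, n_boot=50, seed=1)
        oracle = _mann_whitney_auc(
            [v for v, _ in pairs], [o == "poor" for _, o in pairs], LOWER_PREDICTS_POOR
        )
        assert r.auc == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("direction", [LOWER_PREDICTS_POOR, HIGHER_PREDICTS_POOR])
    def test_auc_equals_mann_whitney_on_random_instances(self, direction):
        rng = np.random.default_rng(99 if direction == LOWER_PREDICTS_POOR else 100)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            n_pos = int(rng.integers(1, n))
            values = np.round(rng.normal(50, 20, n), 1)
            positive = np.zeros(n, bool)
            positive[:n_pos] = True
            pairs = [(float(v), "poor" if p else "good") for v, p in zip(values, positive)]
            r = a.roc(pairs, direction, n_boot=2, seed=0)
            oracle = _mann_whitney_auc(values, positive, direction)
            assert r.auc == pytest.approx(oracle, abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        values = rng.normal(50, 15, 30)
        positive = rng.random(30) < 0.4
        positive[0], positive[1] = True, False  # both classes present
        pairs = [(float(v), "poor" if p else "good") for v, p in zip(values, positive)]
        r = a.roc(pairs, HIGHER_PREDICTS_POOR, n_boot=2, seed=0)
        assert r.auc == pytest.approx(roc_auc_score(positive, values), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(a.ValidationError):
            a.roc([(1.0, "good"), (2.0, "good")], LOWER_PREDICTS_POOR)

    def test_youden_cutoff_ties_break_toward_specificity(self):
        # poor cases low, good cases high, one overlapping value
        pairs = [(10.0, "poor"), (20.0, "poor"), (30.0, "poor"),
                 (30.0, "good"), (40.0, "good"), (50.0, "good")]
        r = a.roc(pairs, LOWER_PREDICTS_POOR, n_boot=10, seed=0)
        called_poor = [v for v, _ in pairs if v < r.chosen_cutoff]
        sens = sum(v in (10.0, 20.0, 30.0) for v in called_poor) / 3
        assert sens >= 2 / 3
        assert 0.0 <= r.auc <= 1.0

    def test_bootstrap_ci_is_seeded_and_ordered(self):
        pairs = [(float(v), "poor" if v < 40 else "good") for v in range(20, 70, 5)]
        r1 = a.roc(pairs, LOWER_PREDICTS_POOR, n_boot=200, seed=42)
        r2 = a.roc(pairs, LOWER_PREDICTS_POOR, n_boot=200, seed=42)
        assert r1.auc_ci == r2.auc_ci
        assert r1.auc_ci[0] <= r1.auc <= r1.auc_ci[1] or r1.auc == 1.0


class TestAucClass:
    @pytest.mark.parametrize(
        "auc,band",
        [(0.60, "low"), (0.70, "low"), (0.868, "moderate"), (0.90, "moderate"),
         (0.955, "high"), (0.91, "high"), (0.3, "low")],
    )
    def test_bands(self, auc, band):
        assert a.auc_class(auc) == band

    def test_out_of_range(self):
        with pytest.raises(a.ValidationError):
            a.auc_class(1.2)


class TestGreenFormula:
    @pytest.mark.parametrize("r2,m,expected", [(1.0, 1, 0), (0.5, 2, 9), (0.673, 2, 5)])
    def test_examples(self, r2, m, expected):
        assert a.green_min_n(r2, m) == expected

    def test_monotone(self):
        assert a.green_min_n(0.4, 2) >= a.green_min_n(0.6, 2)
        assert a.green_min_n(0.5, 3) > a.green_min_n(0.5, 2)

    def test_invalid_r2(self):
        with pytest.raises(a.ValidationError):
            a.green_min_n(0.0, 2)


class TestFitLinear:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        fit = a.fit_linear(2 + 3 * x, pd.DataFrame({"x": x}))
        assert fit.model.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.model.coefficients["x"] == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_predictor_r2_near_zero(self, rng):
        y = rng.normal(size=500)
        x = rng.normal(size=500)
        fit = a.fit_linear(y, pd.DataFrame({"x": x}))
        assert fit.r_squared < 0.05

    def test_rank_deficient_design_errors(self):
        x = np.arange(10.0)
        with pytest.raises(a.ValidationError, match="rank"):
            a.fit_linear(x, pd.DataFrame({"x1": x, "x2": 2 * x}))

    def test_recovers_generating_coefficients_within_ci(self):
        """Noisy data from a known two-predictor model: truth inside the 95% CIs."""
        model = a.MONTH2_MODEL
        dists = {"sfgs2": (55.0, 20.0, 0.0, 100.0), "asfm2": (50.0, 22.0, 0.0, 100.0)}
        df = a.simulate_cohort(37, model, dists, noise_sd=12.0, seed=11)
        fit = a.fit_linear(df["final_sfgs"], df[["sfgs2", "asfm2"]])
        for name, truth in model.coefficients.items():
            lo, hi = fit.conf_int[name]
            assert lo <= truth <= hi


class TestStepwise:
    def test_selects_the_true_predictor(self):
        """The informative predictor always enters; pure-noise candidates enter
        only at the rate the 0.05 entry threshold implies (≈5% each, so exact
        selection of {signal} happens in ≈0.95² ≈ 90% of replicates)."""
        signal_hits = exact_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 200
            x_true = rng.normal(size=n)
            X = pd.DataFrame(
                {"signal": x_true, "noise1": rng.normal(size=n), "noise2": rng.normal(size=n)}
            )
            y = 1.0 + 2.0 * x_true + rng.normal(size=n)
            model = a.stepwise_select(y, X)
            assert model is not None
            signal_hits += "signal" in model.coefficients
            exact_hits += set(model.coefficients) == {"signal"}
        assert signal_hits == 100
        assert exact_hits >= 82  # binomial(100, 0.9025) 3-sigma lower bound

    def test_constant_outcome_selects_nothing(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        assert a.stepwise_select(np.full(50, 7.0), X) is None

    def test_duplicate_informative_predictors_yield_one(self, rng):
        x = rng.normal(size=80)
        y = 3 * x + rng.normal(size=80) * 0.1
        X = pd.DataFrame({"p1": x, "p2": x})
        model = a.stepwise_select(y, X)
        assert model is not None and len(model.coefficients) == 1


class TestCutoffsAndCohort:
    def test_packaged_asfm_cutoffs(self):
        assert a.get_cutoff("asfm", 1).cutoff == 31
        assert a.get_cutoff("asfm", 2).cutoff == 49
        assert a.get_cutoff("enog", 1).direction == HIGHER_PREDICTS_POOR

    def test_classify_by_cutoff_semantics(self):
        c1 = a.get_cutoff("asfm", 1)
        assert a.classify_by_cutoff(30.0, c1) == "poor"  # gross score below 31
        assert a.classify_by_cutoff(31.0, c1) == "good"
        e1 = a.get_cutoff("enog", 1)
        assert a.classify_by_cutoff(95.0, e1) == "poor"  # degeneration above 87

    def test_attrition_arithmetic(self):
        s = a.attrition_summary(enrolled=56, excluded_before_followup=12, lost_to_followup=7)
        assert s.eligible == 44
        assert s.analyzed == 37
        assert s.loss_rate_percent == pytest.approx(100.0 * 7 / 44)

    def test_attrition_rejects_inconsistent_counts(self):
        with pytest.raises(a.ValidationError):
            a.attrition_summary(10, 8, 5)
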