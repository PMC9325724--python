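"""Metric suite, bootstrap CIs, ROC/AUC, curves, ICC(2,1) and CV tuning."""

import numpy as np
import pandas as pd
import pytest

from fetalrad.errors import ContractViolation
from fetalrad.evaluation import (
    ConfusionMatrix,
    binary_metrics,
    bootstrap_ci,
    calibration_gain_lift,
    cv_tune,
    icc_2_1,
    reconstruct_confusion_matrix,
    roc_auc,
    roc_curve_points,
)

from .oracles import auc_pairs_brute, binary_metrics_brute, icc_2_1_brute


class TestBinaryMetrics:
    def test_matches_count_loop_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            y = rng.integers(0, 2, 40)
            p = rng.integers(0, 2, 40)
            cm = ConfusionMatrix.from_predictions(y, p)
            got = binary_metrics(cm)
            want = binary_metrics_brute(y, p)
            for k in want:
                if want[k] is None:
                    assert got[k] is None
                else:
                    assert got[k] == pytest.approx(want[k])

    def test_empty_positive_class_flagged_not_nan(self):
        m = binary_metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=7))
        assert m["sensitivity"] is None
        assert m["specificity"] == pytest.approx(0.7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractViolation):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)

    def test_reconstruction_is_unique_and_consistent(self):
        cm = reconstruct_confusion_matrix(
            18, 67,
            {"sensitivity": 77.78, "specificity": 82.09, "accuracy": 81.18,
             "ppv": 53.85, "npv": 93.22},
        )
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (14, 4, 12, 55)


class TestBootstrapCI:
    @staticmethod
    def _accuracy(yt, ys):
        return float((yt == (ys > 0.5)).mean())

    def test_constant_statistic_zero_width(self, rng):
        y = rng.integers(0, 2, 50)
        lo, hi = bootstrap_ci(lambda yt, ys: 0.42, y, y.astype(float), n_boot=300, seed=0)
        assert lo == hi == 0.42

    def test_seed_determinism(self, rng):
        y = rng.integers(0, 2, 80)
        s = rng.random(80)
        a = bootstrap_ci(self._accuracy, y, s, n_boot=400, seed=5)
        b = bootstrap_ci(self._accuracy, y, s, n_boot=400, seed=5)
        assert a == b

    def test_width_close_to_binomial_for_coin_classifier(self, rng):
        """Accuracy CI of a random classifier on n=100 should be close to
        the analytic binomial width."""
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        acc = self._accuracy(y, s)
        lo, hi = bootstrap_ci(self._accuracy, y, s, n_boot=2000, seed=1)
        analytic = 2 * 1.96 * np.sqrt(acc * (1 - acc) / 100)
        assert abs((hi - lo) - analytic) < 0.25 * analytic


class TestROC:
    def test_perfect_and_tied_scores(self, rng):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        assert roc_auc(np.r_[np.zeros(10), np.ones(10)], y) == 1.0
        assert roc_auc(np.full(20, 0.3), y) == 0.5

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            assert roc_auc(s, y) == pytest.approx(auc_pairs_brute(s, y), abs=1e-12)

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        n1, n0 = y.sum(), (1 - y).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(roc_auc(s, y) - 0.5) < 3 * se

    def test_curve_endpoints(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        pts = roc_curve_points(s, y)
        assert pts["fpr"].iloc[-1] == 1.0 and pts["tpr"].iloc[-1] == 1.0


class TestCurves:
    def test_calibrated_probs_match_observed_rates(self, rng):
        p = rng.random(5000)
        y = (rng.random(5000) < p).astype(int)
        cal = calibration_gain_lift(p, y)["calibration"]
        assert (cal["mean_predicted"] - cal["observed_rate"]).abs().max() < 0.05

    def test_perfect_ranking_gain_geometry(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        p = np.r_[np.linspace(0.9, 1.0, 20), np.linspace(0.0, 0.5, 80)]
        gain = calibration_gain_lift(p, y)["gain"]
        # all positives captured once depth reaches prevalence (0.2)
        at_prev = gain[gain["fraction_cases"] >= 0.2].iloc[0]
        assert at_prev["fraction_positives"] == pytest.approx(1.0)

    def test_random_ranking_lift_near_one(self, rng):
        y = rng.integers(0, 2, 4000)
        p = rng.random(4000)
        lift = calibration_gain_lift(p, y)["lift"]
        deep = lift[lift["fraction_cases"] > 0.3]["lift"]
        assert np.allclose(deep, 1.0, atol=0.15)


class TestICC:
    def test_identical_raters_give_one(self):
        Y = np.tile(np.arange(8, dtype=float)[:, None], (1, 3))
        assert icc_2_1(Y).icc == pytest.approx(1.0)

    def test_matches_anova_sums_oracle_on_toy_table(self, rng):
        Y = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            dtype=float,
        )
        assert icc_2_1(Y).icc == pytest.approx(icc_2_1_brute(Y), abs=1e-9)
        for _ in range(20):
            Yr = rng.random((6, 3)) * 10
            assert icc_2_1(Yr).icc == pytest.approx(icc_2_1_brute(Yr), abs=1e-9)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        Y = rng.random((12, 3)) * 5 + np.arange(12)[:, None]
        res = icc_2_1(Y)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 3),
                "raters": np.tile(np.arange(3), 12),
                "scores": Y.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = row[[c for c in ref.columns if c.startswith("CI95")][0]]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(ci[0], abs=0.01)
        assert res.ci_high == pytest.approx(ci[1], abs=0.01)

    def test_independent_noise_near_zero(self, rng):
        Y = rng.standard_normal((100, 3))
        res = icc_2_1(Y)
        assert abs(res.icc) < 0.2  # ~2 SE at n=100

    def test_shift_invariance_and_rater_bias_penalty(self, rng):
        Y = rng.random((20, 3)) * 4 + np.arange(20)[:, None]
        base = icc_2_1(Y).icc
        assert icc_2_1(Y + 11.5).icc == pytest.approx(base, abs=1e-12)
        biased = Y.copy()
        biased[:, 2] += 6.0  # absolute agreement punishes rater bias
        assert icc_2_1(biased).icc < base

    def test_zero_between_case_variance_flagged(self):
        res = icc_2_1(np.ones((6, 3)))
        assert res.icc == 0.0 and res.degenerate


class TestCVTune:
    @staticmethod
    def _tree_fit_predict(Xtr, ytr, Xte, params, seed):
        from sklearn.tree import DecisionTreeClassifier

        t = DecisionTreeClassifier(max_depth=params["max_depth"], random_state=seed)
        t.fit(Xtr, ytr)
        return t.predict_proba(Xte)[:, 1]

    def test_single_point_grid_returned(self, rng):
        X = rng.random((60, 2))
        y = rng.integers(0, 2, 60)
        best, table = cv_tune(X, y, [{"max_depth": 2}], self._tree_fit_predict, seed=0)
        assert best == {"max_depth": 2}
        assert len(table) == 1

    def test_xor_problem_prefers_deeper_trees(self):
        wins = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.integers(0, 2, (300, 2)).astype(float) + r.normal(0, 0.1, (300, 2))
            y = (np.round(X[:, 0]) != np.round(X[:, 1])).astype(int)
            best, _ = cv_tune(
                X, y, [{"max_depth": 1}, {"max_depth": 3}], self._tree_fit_predict, seed=seed
            )
            wins += best["max_depth"] == 3
        assert wins == 5

    def test_deterministic_given_seed(self, rng):
        X = rng.random((80, 3))
        y = rng.integers(0, 2, 80)
        grid = [{"max_depth": 1}, {"max_depth": 2}]
        _, t1 = cv_tune(X, y, grid, self._tree_fit_predict, seed=7)
        _, t2 = cv_tune(X, y, grid, self._tree_fit_predict, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
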