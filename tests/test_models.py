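"""RUSBoost ensemble and cost-weighted SVM behaviour."""

import numpy as np
import pandas as pd
import pytest

from fetalrad.errors import ContractViolation
from fetalrad.evaluation import roc_auc
from fetalrad.models import (
    rusboost_fit,
    rusboost_predict,
    rusboost_probabilities,
    weighted_svm_fit,
)


@pytest.fixture
def imbalanced_toy(rng):
    """Linearly separable 2-D toy with the study's 159:51 class imbalance."""
    n_neg, n_pos = 159, 51
    X = np.r_[rng.normal(-2, 0.5, (n_neg, 2)), rng.normal(2, 0.5, (n_pos, 2))]
    y = np.r_[np.zeros(n_neg, int), np.ones(n_pos, int)]
    return pd.DataFrame(X, columns=["a", "b"]), y


class TestRUSBoostFit:
    def test_every_round_resample_is_balanced(self, imbalanced_toy):
        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=20, seed=0)
        for entry in model.resample_log:
            assert entry["n_minority"] == 51
            assert entry["n_majority_resampled"] == 51

    def test_separable_toy_perfect_training_accuracy(self, imbalanced_toy):
        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=10, seed=1)
        pred = np.array([r.risk_group == "high" for r in rusboost_predict(model, X)])
        assert np.array_equal(pred.astype(int), y)

    def test_same_seed_identical_rounds_and_predictions(self, imbalanced_toy):
        X, y = imbalanced_toy
        m1 = rusboost_fit(X, y, n_rounds=15, seed=3)
        m2 = rusboost_fit(X, y, n_rounds=15, seed=3)
        assert [a for _, a in m1.rounds] == [a for _, a in m2.rounds]
        assert np.array_equal(rusboost_probabilities(m1, X), rusboost_probabilities(m2, X))

    def test_single_class_rejected(self):
        with pytest.raises(ContractViolation):
            rusboost_fit(np.zeros((10, 2)), np.zeros(10, int), n_rounds=5, seed=0)


class TestRUSBoostPredict:
    def test_probability_bounds_and_cutoff_rule(self, imbalanced_toy, rng):
        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=10, seed=2)
        probes = rng.normal(0, 3, (50, 2))
        for r in rusboost_predict(model, probes):
            assert 0.0 <= r.risk_probability <= 1.0
            assert (r.risk_group == "high") == (r.risk_probability > 0.5)

    def test_equal_scores_give_half_and_low_risk(self, imbalanced_toy):
        """Zero ensemble margin -> probability exactly 0.5 -> low-risk
        (the high-risk rule is a strict inequality)."""
        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=2, seed=0)
        model.rounds = [(model.rounds[0][0], 1.0), (model.rounds[0][0], -1.0)]
        r = rusboost_predict(model, X.iloc[:1])[0]
        assert r.risk_probability == pytest.approx(0.5)
        assert r.risk_group == "low"

    def test_margin_matches_bruteforce_alpha_sum(self, imbalanced_toy, rng):
        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=12, seed=5)
        probes = rng.normal(0, 2, (20, 2))
        results = rusboost_predict(model, probes)
        for i, r in enumerate(results):
            s = [0.0, 0.0]
            for tree, alpha in model.rounds:  # independent vote recount
                s[int(tree.predict(probes[i : i + 1])[0])] += alpha
            assert r.margin == pytest.approx(s[1] - s[0], abs=1e-12)

    def test_feature_name_mismatch_reported(self, imbalanced_toy):
        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=5, seed=0)
        with pytest.raises(ContractViolation, match="missing feature"):
            rusboost_predict(model, pd.DataFrame({"a": [0.0], "wrong": [1.0]}))


class TestSerialization:
    def test_saved_model_round_trips_predictions(self, imbalanced_toy, tmp_path):
        from fetalrad.models import load_model, save_model

        X, y = imbalanced_toy
        model = rusboost_fit(X, y, n_rounds=8, seed=4)
        path = tmp_path / "model.pkl"
        save_model(model, path)
        again = load_model(path)
        assert np.array_equal(
            rusboost_probabilities(model, X), rusboost_probabilities(again, X)
        )
        assert again.feature_names == model.feature_names


class TestWeightedSVM:
    def test_separable_toy_perfect_split(self, rng):
        X = np.r_[rng.normal(-3, 0.3, (40, 1)), rng.normal(3, 0.3, (40, 1))]
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        model = weighted_svm_fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_cost_toward_positives_raises_sensitivity(self, rng):
        """Raising the positive-class cost must not lower held-out
        sensitivity on an overlapping imbalanced problem."""
        def draw(r):
            X = np.r_[r.normal(0, 1, (150, 2)), r.normal(1.0, 1, (50, 2))]
            y = np.r_[np.zeros(150, int), np.ones(50, int)]
            return X, y

        X_tr, y_tr = draw(rng)
        X_te, y_te = draw(rng)
        sens = []
        for ratio in (1.0, 10.0):
            model = weighted_svm_fit(X_tr, y_tr, cost_ratio=ratio)
            pred = model.predict(X_te)
            sens.append(((pred == 1) & (y_te == 1)).sum() / (y_te == 1).sum())
        assert sens[1] >= sens[0]

    def test_deterministic(self, rng):
        X = rng.normal(0, 1, (60, 2))
        y = (X[:, 0] > 0).astype(int)
        s1 = weighted_svm_fit(X, y, seed=1).decision_scores(X)
        s2 = weighted_svm_fit(X, y, seed=1).decision_scores(X)
        assert np.array_equal(s1, s2)

    def test_scores_usable_for_roc(self, rng):
        X = np.c_[rng.normal(0, 1, 200)]
        y = (X[:, 0] + rng.normal(0, 1, 200) > 0.8).astype(int)
        model = weighted_svm_fit(X, y)
        assert roc_auc(model.decision_scores(X), y) > 0.7
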