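"""Imbalance-aware classifiers: RUSBoost and a cost-weighted SVM baseline.

RUSBoost couples discrete two-class AdaBoost with random under-sampling:
each boosting round draws a resample in which the majority class is
under-sampled to the minority count (by default respecting the current
boosting weights), fits a depth-limited decision tree on it, and the
round's weighted error and learner weight ``alpha = 0.5 ln((1-eps)/eps)``
are computed on the full weighted training set. The ensemble score for a
class is the sum of alphas of trees voting for it; the risk probability is
the softmax of the two class scores, and the 0.5 cut-off assigns the
high-risk group (strictly greater than 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ContractViolation, FetalRadError

#: Error floor / ceiling keeping alpha finite.
EPS_FLOOR = 1e-10
MAX_REDRAWS = 10


@dataclass(frozen=True)
class PredictionResult:
    risk_probability: float
    risk_group: str  # "high" | "low"
    margin: float  # score(positive) - score(negative)


@dataclass
class RUSBoostModel:
    rounds: list[tuple[DecisionTreeClassifier, float]]
    feature_names: list[str] | None
    n_rounds: int
    max_depth: int
    seed: int
    resample_log: list[dict] = field(default_factory=list)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class alpha-vote scores, shape (n, 2) for classes (0, 1)."""
        X = np.asarray(X, float)
        scores = np.zeros((X.shape[0], 2))
        for tree, alpha in self.rounds:
            pred = tree.predict(X).astype(int)
            scores[np.arange(X.shape[0]), pred] += alpha
        return scores


def _validate_X(X, model: RUSBoostModel) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if model.feature_names is not None:
            missing = [n for n in model.feature_names if n not in X.columns]
            if missing:
                raise ContractViolation(f"missing feature columns: {missing}")
            X = X[model.feature_names]
        return X.to_numpy(float)
    X = np.asarray(X, float)
    if model.feature_names is not None and X.shape[1] != len(model.feature_names):
        raise ContractViolation(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    return X


def rusboost_fit(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_rounds: int = 100,
    seed: int = 0,
    max_depth: int = 3,
    weight_aware: bool = True,
) -> RUSBoostModel:
    """Fit a RUSBoost ensemble on binary labels.

    ``weight_aware`` draws each round's majority under-sample with
    probability proportional to the current boosting weights (without
    replacement); ``False`` draws uniformly. Rounds whose weighted error on
    the full set reaches 0.5 are re-drawn up to 10 times, then training
    stops with whatever rounds were retained. Deterministic given ``seed``.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or set(classes) != {0, 1}:
        raise ContractViolation("y must contain both classes encoded 0/1")
    if n_rounds < 1:
        raise ContractViolation("n_rounds must be >= 1")
    minority = int(classes[np.argmin(counts)])
    n_min = int(counts.min())
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y != minority)

    rng = np.random.default_rng(seed)
    n = len(y)
    w = np.full(n, 1.0 / n)
    sign = np.where(y == 1, 1.0, -1.0)
    model = RUSBoostModel(
        rounds=[], feature_names=names, n_rounds=n_rounds, max_depth=max_depth, seed=seed
    )
    for r in range(n_rounds):
        fitted = None
        for _ in range(MAX_REDRAWS):
            if weight_aware:
                p_maj = w[idx_maj] / w[idx_maj].sum()
                take = rng.choice(idx_maj, size=n_min, replace=False, p=p_maj)
            else:
                take = rng.choice(idx_maj, size=n_min, replace=False)
            sel = np.concatenate([idx_min, take])
            tree = DecisionTreeClassifier(
                max_depth=max_depth, random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(Xa[sel], y[sel], sample_weight=w[sel] / w[sel].sum())
            pred = tree.predict(Xa).astype(int)
            eps = float(w[pred != y].sum())
            if eps < 0.5:
                fitted = (tree, pred, eps)
                break
        if fitted is None:
            if not model.rounds:
                raise FetalRadError(
                    "RUSBoost training failed: every redraw had weighted error >= 0.5"
                )
            break
        tree, pred, eps = fitted
        eps = min(max(eps, EPS_FLOOR), 1.0 - EPS_FLOOR)
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        model.rounds.append((tree, float(alpha)))
        model.resample_log.append(
            {
                "round": r,
                "n_minority": n_min,
                "n_majority_resampled": n_min,
                "weighted_error": eps,
                "alpha": float(alpha),
            }
        )
        h = np.where(pred == 1, 1.0, -1.0)
        w *= np.exp(-alpha * sign * h)
        w /= w.sum()
    return model


def rusboost_predict(
    model: RUSBoostModel, X: pd.DataFrame | np.ndarray
) -> list[PredictionResult]:
    """Softmax-normalized NRM risk probability and high/low-risk call.

    Risk probability is the positive-class component of the softmax over
    the two alpha-vote scores; a probability strictly greater than 0.5 is
    called high-risk (exactly 0.5 is low-risk).
    """
    Xa = _validate_X(X, model)
    if Xa.ndim == 1:
        Xa = Xa[None, :]
    scores = model.decision_scores(Xa)
    margin = scores[:, 1] - scores[:, 0]
    # softmax over the two class scores = logistic of the margin
    from scipy.special import expit

    prob = expit(margin)
    return [
        PredictionResult(
            risk_probability=float(p),
            risk_group="high" if p > 0.5 else "low",
            margin=float(m),
        )
        for p, m in zip(prob, margin)
    ]


def rusboost_probabilities(model: RUSBoostModel, X) -> np.ndarray:
    return np.array([r.risk_probability for r in rusboost_predict(model, X)])


MODEL_FORMAT_VERSION = 1


def save_model(model: RUSBoostModel, path) -> None:
    """Serialize a fitted ensemble to a versioned pickle archive."""
    import pickle
    from pathlib import Path

    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model}
    Path(path).write_bytes(pickle.dumps(payload))


def load_model(path) -> RUSBoostModel:
    import pickle
    from pathlib import Path

    payload = pickle.loads(Path(path).read_bytes())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ContractViolation(f"unsupported model format version: {version}")
    return payload["model"]


@dataclass
class WeightedSVM:
    svc: SVC
    feature_names: list[str] | None
    center: np.ndarray
    scale: np.ndarray

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.feature_names:
            X = X[self.feature_names]
        Xa = np.asarray(X, float)
        return (Xa - self.center) / self.scale

    def decision_scores(self, X) -> np.ndarray:
        return self.svc.decision_function(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return self.svc.predict(self._prepare(X))


def weighted_svm_fit(
    X_clinical: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cost_ratio: float | None = None,
    seed: int = 0,
) -> WeightedSVM:
    """Cost-weighted SVM on the clinical covariates (GA, complication).

    ``cost_ratio`` is the positive-class misclassification cost relative to
    the negative class; the default is the inverse class frequency, which
    makes the classifier focus on the rare positive cases. Features are
    standardized internally (the RBF kernel is scale-sensitive). The
    decision function provides the continuous score used for ROC analysis.
    """
    y = np.asarray(y, int)
    if len(np.unique(y)) != 2:
        raise ContractViolation("y must contain both classes")
    names = list(X_clinical.columns) if isinstance(X_clinical, pd.DataFrame) else None
    Xa = X_clinical.to_numpy(float) if isinstance(X_clinical, pd.DataFrame) else np.asarray(X_clinical, float)
    if cost_ratio is None:
        cost_ratio = float((y == 0).sum() / max((y == 1).sum(), 1))
    center = Xa.mean(axis=0)
    scale = Xa.std(axis=0)
    scale[scale == 0] = 1.0
    svc = SVC(kernel="rbf", class_weight={0: 1.0, 1: cost_ratio}, random_state=seed)
    svc.fit((Xa - center) / scale, y)
    return WeightedSVM(svc=svc, feature_names=names, center=center, scale=scale)
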