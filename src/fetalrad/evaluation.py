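"""Performance machinery: confusion-matrix metrics with bootstrap CIs,
ROC/AUC, calibration/gain/lift curves, ICC(2,1) feature stability, and
bootstrap tenfold cross-validation for parameter tuning."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation

DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractViolation("confusion-matrix counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )


def binary_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, PPV, NPV as fractions in [0, 1].

    A metric whose denominator is empty is reported as ``None`` rather
    than NaN-propagated.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    total = cm.tp + cm.fp + cm.fn + cm.tn
    return {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "accuracy": ratio(cm.tp + cm.tn, total),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
    }


def reconstruct_confusion_matrix(
    n_pos: int,
    n_neg: int,
    printed: dict[str, float],
    decimals: int = 2,
) -> ConfusionMatrix:
    """Integer confusion matrix consistent with printed percentage metrics.

    Exhaustively searches TP in 0..n_pos and TN in 0..n_neg for the matrix
    whose metrics round (to ``decimals``) to every printed percentage
    supplied in ``printed`` (keys as in :func:`binary_metrics`, values in
    percent). Raises if no matrix or more than one matrix matches.
    """
    hits = []
    for tp, tn in product(range(n_pos + 1), range(n_neg + 1)):
        cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
        m = binary_metrics(cm)
        ok = True
        for key, want in printed.items():
            got = m[key]
            if got is None or round(got * 100.0, decimals) != round(want, decimals):
                ok = False
                break
        if ok:
            hits.append(cm)
    if len(hits) != 1:
        raise ContractViolation(
            f"printed metrics match {len(hits)} confusion matrices, expected exactly 1"
        )
    return hits[0]


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float | None],
    y_true: np.ndarray,
    y_score: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a per-cohort statistic.

    Cases are resampled with replacement; resamples on which the statistic
    is undefined (e.g. a single-class draw for AUC) are skipped.
    """
    if n_boot < 200:
        raise ContractViolation(f"n_boot must be >= 200, got {n_boot}")
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(y_true[idx], y_score[idx])
        except ContractViolation:
            continue
        if v is not None and np.isfinite(v):
            vals.append(v)
    if not vals:
        raise ContractViolation("statistic undefined on every bootstrap resample")
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney) estimator with tie correction."""
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ContractViolation("both classes required for AUC")
    ranks = stats.rankdata(scores)  # midranks handle ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """(threshold, FPR, TPR) at every distinct score threshold."""
    labels = np.asarray(labels, int)
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    s = np.asarray(scores, float)[order]
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    n1, n0 = max(tps[-1], 1), max(fps[-1], 1)
    return pd.DataFrame(
        {
            "threshold": s[distinct],
            "fpr": fps[distinct] / n0,
            "tpr": tps[distinct] / n1,
        }
    )


@dataclass(frozen=True)
class MetricsReport:
    """Point estimates with percentile-bootstrap 95% CIs, as fractions."""

    table: pd.DataFrame  # metric, estimate, ci_low, ci_high

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            row.metric: {"estimate": row.estimate, "ci_low": row.ci_low, "ci_high": row.ci_high}
            for row in self.table.itertuples()
        }


def metrics_report(
    y_true: np.ndarray,
    y_score: np.ndarray,
    threshold: float = 0.5,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MetricsReport:
    """Full metric suite (sens/spec/acc/PPV/NPV/AUC) with 95% CIs.

    Predictions are called positive when the score is strictly greater
    than ``threshold``, matching the high-risk rule.
    """

    def make_stat(key: str) -> Callable:
        def stat(yt: np.ndarray, ys: np.ndarray) -> float | None:
            cm = ConfusionMatrix.from_predictions(yt, (ys > threshold).astype(int))
            return binary_metrics(cm)[key]

        return stat

    def auc_stat(yt: np.ndarray, ys: np.ndarray) -> float:
        return roc_auc(ys, yt)

    rows = []
    stats_map = {k: make_stat(k) for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv")}
    stats_map["auc"] = auc_stat
    for i, (name, fn) in enumerate(stats_map.items()):
        est = fn(np.asarray(y_true), np.asarray(y_score))
        lo, hi = bootstrap_ci(fn, y_true, y_score, n_boot=n_boot, seed=seed + i)
        rows.append((name, est, lo, hi))
    return MetricsReport(
        table=pd.DataFrame(rows, columns=["metric", "estimate", "ci_low", "ci_high"])
    )


def calibration_gain_lift(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> dict[str, pd.DataFrame]:
    """Decile calibration, cumulative gain and lift curve data points.

    Calibration bins predicted probabilities into ``n_bins`` equal-width
    bins (empty bins dropped); gain/lift rank cases by descending
    probability and report, at each depth, the captured fraction of
    positives and its ratio to the baseline prevalence.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    if probs.min() < 0 or probs.max() > 1:
        raise ContractViolation("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    cal_rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        cal_rows.append(
            (0.5 * (edges[b] + edges[b + 1]), probs[sel].mean(), labels[sel].mean(), int(sel.sum()))
        )
    calibration = pd.DataFrame(
        cal_rows, columns=["bin_center", "mean_predicted", "observed_rate", "n"]
    )
    order = np.argsort(-probs, kind="stable")
    y_sorted = labels[order]
    n = len(labels)
    n_pos = max(int(labels.sum()), 1)
    depth = np.arange(1, n + 1) / n
    gain = np.cumsum(y_sorted) / n_pos
    gain_df = pd.DataFrame({"fraction_cases": depth, "fraction_positives": gain})
    lift_df = pd.DataFrame({"fraction_cases": depth, "lift": gain / depth})
    return {"calibration": calibration, "gain": gain_df, "lift": lift_df}


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is cases x raters (here the three delineations). With mean
    squares from the two-way ANOVA (rows = cases, columns = raters):
    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    The 95% CI follows the Shrout-Fleiss F-based construction. Zero
    between-case variance is reported as ICC 0 with the degenerate flag.
    """
    Y = np.asarray(ratings, float)
    n, k = Y.shape
    if n < 5:
        raise ContractViolation(f"need >= 5 cases, got {n}")
    if k < 2:
        raise ContractViolation("need >= 2 raters")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((Y - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= 1e-30:
        return ICCResult(icc=0.0, ci_low=0.0, ci_high=0.0, degenerate=True)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI for the absolute-agreement single-measure ICC
    if mse <= 0:
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc), degenerate=False)
    fj = msc / mse
    df_e = (n - 1) * (k - 1)
    core = n * (1.0 + (k - 1) * icc) - k * icc
    v = (
        df_e * (k * icc * fj + core) ** 2
        / ((n - 1) * k**2 * icc**2 * fj**2 + core**2)
    )
    f_u = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    lo, hi = float(min(lo, icc)), float(min(max(hi, icc), 1.0))
    return ICCResult(icc=float(icc), ci_low=lo, ci_high=hi)


def icc_table(
    feature_frames: dict[str, pd.DataFrame], features: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature ICC(2,1) across delineation variants.

    ``feature_frames`` maps delineation name -> (cases x features) frame
    with a shared index; returns a frame with icc, ci_low, ci_high per
    feature.
    """
    frames = list(feature_frames.values())
    features = features or list(frames[0].columns)
    rows = []
    for f in features:
        ratings = np.column_stack([fr[f].to_numpy(float) for fr in frames])
        res = icc_2_1(ratings)
        rows.append((f, res.icc, res.ci_low, res.ci_high, res.degenerate))
    return pd.DataFrame(rows, columns=["feature", "icc", "ci_low", "ci_high", "degenerate"])


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment; guards folds against single-class."""
    y = np.asarray(y, int)
    fold_of = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def cv_tune(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    param_grid: list[dict],
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray, dict, int], np.ndarray],
    seed: int = 0,
    n_folds: int = 10,
    n_bootstrap: int = 3,
) -> tuple[dict, pd.DataFrame]:
    """Bootstrap tenfold cross-validation over a parameter grid.

    For each of ``n_bootstrap`` bootstrap resamples of the training cases,
    a stratified ``n_folds``-fold split is scored out-of-fold; the grid
    point with the highest mean AUC wins (ties broken by grid order). The
    full result table is returned alongside the chosen parameters.
    ``fit_predict(X_train, y_train, X_test, params, seed)`` must return
    continuous scores for ``X_test``.
    """
    if not param_grid:
        raise ContractViolation("parameter grid must be non-empty")
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, int)
    rng = np.random.default_rng(seed)
    rows = []
    for gi, params in enumerate(param_grid):
        aucs = []
        for b in range(n_bootstrap):
            idx = rng.integers(0, len(y), size=len(y))
            # a resample must keep both classes; redraw if not
            for _ in range(20):
                if len(np.unique(y[idx])) == 2:
                    break
                idx = rng.integers(0, len(y), size=len(y))
            Xb, yb = Xa[idx], y[idx]
            folds = _stratified_folds(yb, n_folds, rng)
            scores = np.zeros(len(yb))
            for f, test_idx in enumerate(folds):
                if test_idx.size == 0:
                    continue
                train_idx = np.setdiff1d(np.arange(len(yb)), test_idx)
                fold_seed = int(rng.integers(0, 2**31 - 1))
                scores[test_idx] = fit_predict(
                    Xb[train_idx], yb[train_idx], Xb[test_idx], params, fold_seed
                )
            try:
                aucs.append(roc_auc(scores, yb))
            except ContractViolation:
                continue
        rows.append({"grid_index": gi, "mean_auc": float(np.mean(aucs)), **params})
    table = pd.DataFrame(rows)
    best = int(table["mean_auc"].idxmax())
    return param_grid[best], table
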