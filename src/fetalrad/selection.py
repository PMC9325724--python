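"""Univariate screening and out-of-bag permutation-importance selection.

Screening (two-sample t-test per continuous radiomics feature, chi-squared
for the binary clinical covariates) is descriptive only: the selected set
is the top-k of the permutation-importance ranking, to which the two
clinical covariates (gestational age and the GDM/PE flag) are always
appended — the reported selected set includes features whose univariate p
exceeds 0.05.

Importance follows the classical random-forest recipe: a bagged regression
forest on the 0/1 labels; per tree the out-of-bag squared error is
computed before and after permuting one feature's out-of-bag values, and a
feature's importance is the mean error increase across trees (normalized
by the across-tree standard deviation by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigurationError, ContractViolation
from .features.catalog import CLINICAL_FEATURES

DEFAULT_N_TREES = 500


@dataclass(frozen=True)
class ScreeningReport:
    table: pd.DataFrame  # feature, test, statistic, p_value


@dataclass(frozen=True)
class ImportanceRanking:
    table: pd.DataFrame  # feature, importance, raw_importance, rank
    n_trees: int
    seed: int

    def top(self, k: int) -> list[str]:
        return self.table.sort_values("rank")["feature"].head(k).tolist()


def univariate_screen(
    features: pd.DataFrame,
    labels: np.ndarray,
    categorical: tuple[str, ...] = ("GDM or PE",),
) -> ScreeningReport:
    """Per-feature two-sided tests between the NRM and normal groups.

    Continuous columns get Welch-free pooled two-sample t-tests; columns
    named in ``categorical`` get a chi-squared test on the 2x2 table
    without continuity correction. Degenerate columns (no variance in
    either group, or an empty table margin) are reported with statistic 0
    and p = 1.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ContractViolation("both classes must be present for screening")
    g1 = features.loc[labels == 1]
    g0 = features.loc[labels == 0]
    if len(g0) < 2 or len(g1) < 2:
        raise ContractViolation("need >= 2 samples per class for the t-test")
    rows = []
    for col in features.columns:
        if col in categorical:
            tab = pd.crosstab(features[col], labels)
            if tab.shape == (2, 2) and (tab.values.sum(axis=0) > 0).all():
                chi2, p, _, _ = stats.chi2_contingency(tab.values, correction=False)
            else:
                chi2, p = 0.0, 1.0
            rows.append((col, "chi-squared", float(chi2), float(p)))
        else:
            a, b = g1[col].to_numpy(float), g0[col].to_numpy(float)
            if a.std() == 0 and b.std() == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b)
                if not np.isfinite(p):
                    t, p = 0.0, 1.0
            rows.append((col, "t-test", float(t), float(p)))
    return ScreeningReport(
        table=pd.DataFrame(rows, columns=["feature", "test", "statistic", "p_value"])
    )


def _bootstrap_indices(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
    return idx, oob


def oob_importance(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    normalize: bool = True,
) -> ImportanceRanking:
    """Permutation importance from out-of-bag error of a regression forest.

    Each tree is fit on a bootstrap sample of the 0/1-encoded labels with
    ``mtry = floor(sqrt(p))`` candidate features per split and unlimited
    depth. Importance is the mean across trees of the out-of-bag
    squared-error increase when one feature's out-of-bag values are
    permuted; with ``normalize`` the mean is divided by the across-tree
    standard deviation (features never used by any tree keep importance
    0). Ranks break ties by column order, so the ranking is a permutation
    of 1..p and is reproducible given the seed.
    """
    if n_trees < 50:
        raise ConfigurationError(f"n_trees must be >= 50, got {n_trees}")
    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else [
        f"f{j}" for j in range(X.shape[1])
    ]
    y = np.asarray(labels, float)
    n, p = X.shape
    if p == 0:
        raise ContractViolation("no features supplied")
    rng = np.random.default_rng(seed)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    increases = np.full((n_trees, p), np.nan)
    for t in range(n_trees):
        boot, oob = _bootstrap_indices(rng, n)
        if oob.size < 2:
            continue
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeRegressor(max_features="sqrt", random_state=tree_seed)
        tree.fit(X[boot], y[boot])
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        X_oob = X32[oob].copy()
        base_err = float(((tree.tree_.predict(X_oob)[:, 0] - y[oob]) ** 2).mean())
        increases[t, :] = 0.0
        for j in used:
            saved = X_oob[:, j].copy()
            X_oob[:, j] = saved[rng.permutation(oob.size)]
            perm_err = float(((tree.tree_.predict(X_oob)[:, 0] - y[oob]) ** 2).mean())
            X_oob[:, j] = saved
            increases[t, j] = perm_err - base_err
    raw = np.nanmean(increases, axis=0)
    sd = np.nanstd(increases, axis=0)
    if normalize:
        imp = np.divide(raw, sd, out=np.zeros_like(raw), where=sd > 0)
    else:
        imp = raw
    order = np.lexsort((np.arange(p), -imp))  # ties broken by column order
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {"feature": names, "importance": imp, "raw_importance": raw, "rank": rank}
    )
    return ImportanceRanking(table=table, n_trees=n_trees, seed=seed)


def select_features(
    ranking: ImportanceRanking,
    k_radiomics: int = 20,
    clinical: tuple[str, ...] = CLINICAL_FEATURES,
) -> list[str]:
    """Top-k radiomics features by importance plus the clinical covariates.

    Clinical columns present in the ranking are excluded from the top-k
    pool and appended unconditionally, giving ``k + 2`` names by default.
    """
    pool = ranking.table[~ranking.table["feature"].isin(clinical)]
    if k_radiomics > len(pool):
        raise ConfigurationError(
            f"k_radiomics={k_radiomics} exceeds the {len(pool)} available features"
        )
    top = pool.sort_values("rank")["feature"].head(k_radiomics).tolist()
    return top + list(clinical)
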