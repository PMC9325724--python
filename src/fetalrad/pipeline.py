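"""End-to-end experiment: simulate -> extract -> select -> train -> evaluate.

Reproduces the study design on synthetic cohorts: an independent training
and testing cohort (emulating the two-machine / two-operator acquisition),
three ROI delineation variants per case (free-hand A and B, 40x40 square),
feature selection on the radiologist-A training features, a cost-weighted
SVM for the clinical covariates and RUSBoost for the radiomics and combined
feature sets, and the full metric suite for every (feature set, split,
delineation) cell plus the per-feature ICC(2,1) stability table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import MetricsReport, cv_tune, icc_table, metrics_report
from .features import extract_all
from .features.catalog import CLINICAL_FEATURES
from .models import (
    rusboost_fit,
    rusboost_probabilities,
    weighted_svm_fit,
)
from .selection import oob_importance, select_features, univariate_screen
from .synthetic import CohortConfig, SyntheticCase, generate_cohort

log = logging.getLogger(__name__)

DELINEATIONS = ("freehand_A", "freehand_B", "square")
FEATURE_SETS = ("clinical", "radiomics", "combined")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one synthetic replication of the study."""

    n_train: int = 210
    n_test: int = 85
    nrm_prevalence: float = 0.234
    complication_rate: float = 0.332
    texture_effect: float = 1.0
    image_size: tuple[int, int] = (128, 128)
    n_levels: int = 16
    k_radiomics: int = 20
    n_importance_trees: int = 500
    n_rusboost_rounds: int = 50
    tune_depths: tuple[int, ...] = (1, 2, 3)  # bootstrap-CV grid; empty = no tuning
    rusboost_depth: int = 2  # used when tune_depths is empty
    n_boot: int = 1000
    delineations: tuple[str, ...] = DELINEATIONS
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ConfigurationError("split sizes must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    selected_features: list[str]
    screening: pd.DataFrame
    metrics: dict[tuple[str, str, str], MetricsReport]  # (feature_set, split, delineation)
    icc: pd.DataFrame
    feature_frames: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)

    def auc(self, feature_set: str, split: str, delineation: str = "freehand_A") -> float:
        rep = self.metrics[(feature_set, split, delineation)]
        return float(rep.table.set_index("metric").loc["auc", "estimate"])


def extract_cohort_features(
    cases: list[SyntheticCase],
    delineation: str = "freehand_A",
    n_levels: int = 16,
) -> pd.DataFrame:
    """Catalog feature frame for one delineation, plus GA / complication /
    label columns."""
    attr = {
        "freehand_A": "mask_freehand_A",
        "freehand_B": "mask_freehand_B",
        "square": "mask_square",
    }[delineation]
    rows = []
    for c in cases:
        vals = extract_all(c.image, getattr(c, attr), n_levels=n_levels)
        vals["GA"] = float(c.ga_weeks)
        vals["GDM or PE"] = float(c.complication)
        vals["label"] = int(c.label)
        rows.append(vals)
    return pd.DataFrame(rows, index=[c.case_id for c in cases])


def _clinical_scores(model, X: pd.DataFrame) -> np.ndarray:
    return model.decision_scores(X)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full pipeline on independently drawn train / test cohorts."""
    t0 = time.time()
    train_cfg = CohortConfig(
        n_cases=config.n_train,
        nrm_prevalence=config.nrm_prevalence,
        complication_rate=config.complication_rate,
        image_size=config.image_size,
        texture_effect=config.texture_effect,
        seed=config.seed,
    )
    test_cfg = CohortConfig(
        n_cases=config.n_test,
        nrm_prevalence=config.nrm_prevalence,
        complication_rate=config.complication_rate,
        image_size=config.image_size,
        texture_effect=config.texture_effect,
        seed=config.seed + 500_000,
    )
    train_cases = generate_cohort(train_cfg)
    test_cases = generate_cohort(test_cfg)
    log.info("cohorts generated (%.1f s)", time.time() - t0)

    frames: dict[str, dict[str, pd.DataFrame]] = {"train": {}, "test": {}}
    for d in config.delineations:
        frames["train"][d] = extract_cohort_features(train_cases, d, config.n_levels)
        frames["test"][d] = extract_cohort_features(test_cases, d, config.n_levels)
    log.info("features extracted (%.1f s)", time.time() - t0)

    ref = frames["train"]["freehand_A"]
    y_train = ref["label"].to_numpy(int)
    radiomics_cols = [c for c in ref.columns if c not in ("label",) + CLINICAL_FEATURES]
    screening = univariate_screen(
        ref[radiomics_cols + list(CLINICAL_FEATURES)], y_train
    ).table
    ranking = oob_importance(
        ref[radiomics_cols], y_train,
        n_trees=config.n_importance_trees, seed=config.seed,
    )
    selected = select_features(ranking, k_radiomics=config.k_radiomics)
    radiomics_sel = [f for f in selected if f not in CLINICAL_FEATURES]
    log.info("selection done (%.1f s)", time.time() - t0)

    metrics: dict[tuple[str, str, str], MetricsReport] = {}
    for d in config.delineations:
        tr, te = frames["train"][d], frames["test"][d]
        y_tr, y_te = tr["label"].to_numpy(int), te["label"].to_numpy(int)
        columns = {
            "clinical": list(CLINICAL_FEATURES),
            "radiomics": radiomics_sel,
            "combined": radiomics_sel + list(CLINICAL_FEATURES),
        }
        models = {}
        models["clinical"] = weighted_svm_fit(
            tr[columns["clinical"]], y_tr, seed=config.seed
        )
        for fs in ("radiomics", "combined"):
            if config.tune_depths:
                grid = [{"max_depth": d} for d in config.tune_depths]

                def fit_predict(Xtr, ytr_, Xte, params, fold_seed):
                    m = rusboost_fit(
                        Xtr, ytr_, n_rounds=config.n_rusboost_rounds,
                        seed=fold_seed, max_depth=params["max_depth"],
                    )
                    return rusboost_probabilities(m, Xte)

                best, _ = cv_tune(
                    tr[columns[fs]], y_tr, grid, fit_predict,
                    seed=config.seed, n_bootstrap=2,
                )
                depth = best["max_depth"]
            else:
                depth = config.rusboost_depth
            models[fs] = rusboost_fit(
                tr[columns[fs]], y_tr,
                n_rounds=config.n_rusboost_rounds,
                seed=config.seed,
                max_depth=depth,
            )
        for split, frame, y in (("train", tr, y_tr), ("test", te, y_te)):
            for fs in FEATURE_SETS:
                if fs == "clinical":
                    scores = _clinical_scores(models[fs], frame[columns[fs]])
                    threshold = 0.0
                else:
                    scores = rusboost_probabilities(models[fs], frame[columns[fs]])
                    threshold = 0.5
                metrics[(fs, split, d)] = metrics_report(
                    y, scores, threshold=threshold,
                    n_boot=config.n_boot, seed=config.seed,
                )
    log.info("models evaluated (%.1f s)", time.time() - t0)

    if len(config.delineations) >= 2:
        all_frames = {
            d: pd.concat([frames["train"][d], frames["test"][d]])
            for d in config.delineations
        }
        icc = icc_table(all_frames, features=radiomics_sel)
    else:
        icc = pd.DataFrame(columns=["feature", "icc", "ci_low", "ci_high", "degenerate"])

    report = ExperimentReport(
        config=config,
        selected_features=selected,
        screening=screening,
        metrics=metrics,
        icc=icc,
        feature_frames=frames,
    )
    if config.out_dir:
        _write_report(report)
    return report


def ordering_study(
    n_seeds: int = 10,
    texture_effect: float = 2.0,
    n_train: int = 210,
    n_test: int = 200,
    image_size: tuple[int, int] = (128, 128),
    n_importance_trees: int = 300,
    n_rounds: int = 50,
    tune_depths: tuple[int, ...] = (1, 2),
    base_seed: int = 0,
) -> pd.DataFrame:
    """Held-out AUC of the three feature sets across generator seeds.

    Replicates the model-comparison design: per seed, independent train /
    test cohorts with a strong texture signal, selection on the training
    radiologist-A features, then held-out AUC for the clinical SVM, the
    radiomics RUSBoost and the combined RUSBoost. Returns one row per seed
    with an ``ordered`` flag for the clinical < radiomics < combined
    pattern. Uses a larger test cohort than the study split so the AUC
    ranking is not swamped by held-out sampling noise.
    """
    from .evaluation import roc_auc

    rows = []
    for k in range(n_seeds):
        seed = base_seed + k + 1
        tr_cases = generate_cohort(CohortConfig(
            n_cases=n_train, seed=seed, image_size=image_size,
            texture_effect=texture_effect,
        ))
        te_cases = generate_cohort(CohortConfig(
            n_cases=n_test, seed=seed + 500_000, image_size=image_size,
            texture_effect=texture_effect,
        ))
        tr = extract_cohort_features(tr_cases)
        te = extract_cohort_features(te_cases)
        y_tr, y_te = tr["label"].to_numpy(int), te["label"].to_numpy(int)
        rad = [c for c in tr.columns if c not in ("label",) + CLINICAL_FEATURES]
        ranking = oob_importance(tr[rad], y_tr, n_trees=n_importance_trees, seed=seed)
        sel = [f for f in select_features(ranking) if f not in CLINICAL_FEATURES]
        columns = {
            "clinical": list(CLINICAL_FEATURES),
            "radiomics": sel,
            "combined": sel + list(CLINICAL_FEATURES),
        }
        svm = weighted_svm_fit(tr[columns["clinical"]], y_tr, seed=seed)
        aucs = {"clinical": roc_auc(svm.decision_scores(te[columns["clinical"]]), y_te)}
        for fs in ("radiomics", "combined"):
            grid = [{"max_depth": d} for d in tune_depths]

            def fit_predict(Xtr, ytr_, Xte, params, fold_seed):
                m = rusboost_fit(Xtr, ytr_, n_rounds=n_rounds,
                                 seed=fold_seed, max_depth=params["max_depth"])
                return rusboost_probabilities(m, Xte)

            best, _ = cv_tune(tr[columns[fs]], y_tr, grid, fit_predict,
                              seed=seed, n_bootstrap=2)
            model = rusboost_fit(tr[columns[fs]], y_tr, n_rounds=n_rounds,
                                 seed=seed, max_depth=best["max_depth"])
            aucs[fs] = roc_auc(rusboost_probabilities(model, te[columns[fs]]), y_te)
        rows.append({
            "seed": seed,
            "auc_clinical": aucs["clinical"],
            "auc_radiomics": aucs["radiomics"],
            "auc_combined": aucs["combined"],
            "ordered": aucs["clinical"] < aucs["radiomics"] < aucs["combined"],
        })
        log.info("ordering seed %d: %s", seed, rows[-1])
    return pd.DataFrame(rows)


def _write_report(report: ExperimentReport) -> None:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report.config.config_hash(), "seed": report.config.seed}
    (out / "config.json").write_text(
        json.dumps({**asdict(report.config), **stamp}, indent=2, default=str)
    )
    (out / "selected_features.json").write_text(
        json.dumps({**stamp, "features": report.selected_features}, indent=2)
    )
    report.screening.to_csv(out / "screening.csv", index=False)
    report.icc.to_csv(out / "icc.csv", index=False)
    for split, by_delin in report.feature_frames.items():
        for d, frame in by_delin.items():
            frame.to_csv(out / f"features_{split}_{d}.csv")
    panels = {
        f"{fs}.{split}.{d}": rep.as_dict()
        for (fs, split, d), rep in report.metrics.items()
    }
    (out / "metrics.json").write_text(json.dumps({**stamp, "panels": panels}, indent=2))
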