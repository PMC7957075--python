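"""Random-forest discrimination of m6A regions from matched controls.

Positives are m6A regions bound by at least one RBP; each of the repeated
control sets is a stratum-matched, equal-size draw from the control pool.
Features are the binary RBP-binding indicators, so feature importance (mean
decrease in impurity) measures how much each RBP's binding pattern carries
about methylation status — in either direction: an RBP repelled by m6A is as
informative as a reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .core import BindingMatrix, ControlPool, InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    n_control_sets: int = 10
    train_frac: float = 0.8
    cv_folds: int = 5
    mtry: int | str = "sqrt"
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ParameterError("train_frac must be in (0, 1)")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.n_control_sets < 1 or self.n_trees < 1:
            raise ParameterError("n_control_sets and n_trees must be >= 1")


@dataclass
class ClassifierRun:
    """Held-out evaluation of one control-set draw."""

    control_set_id: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    cv_accuracy: float
    auroc: float
    importance: Mapping[str, float]
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ParameterError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ParameterError("accuracy undefined for all-zero confusion counts")
    return (tp + tn) / total


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def default_mtry(n_features: int) -> int:
    """floor(sqrt(n_features)), at least 1 — the usual forest default."""
    if n_features < 1:
        raise ParameterError("n_features must be >= 1")
    return max(1, int(np.sqrt(n_features)))


def build_dataset(
    bm_m6a: BindingMatrix,
    bm_pool: BindingMatrix,
    pool: ControlPool,
    control_set_id: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble one balanced feature matrix.

    Positives: m6A regions with >= 1 bound RBP (all-zero rows excluded).
    Controls: a stratum-matched draw of equal size from the pool, matching the
    *positive* rows' stratum composition; control rows are not filtered for
    all-zero features. Deterministic in (seed, control_set_id).
    """
    if list(bm_m6a.rbps) != list(bm_pool.rbps):
        raise InputError("m6A and pool binding matrices must share the RBP universe")
    pos_mask = bm_m6a.bound.sum(axis=1) > 0
    pos_idx = np.flatnonzero(pos_mask)
    if len(pos_idx) < 10:
        raise ParameterError(f"too few positive regions ({len(pos_idx)})")
    need: dict[str, int] = {}
    for i in pos_idx:
        s = bm_m6a.regions[i].stratum
        need[s] = need.get(s, 0) + 1
    strata = pool.stratum_indices()
    rng = np.random.default_rng([seed, control_set_id])
    ctrl_parts = []
    for stratum, n in sorted(need.items()):
        avail = strata.get(stratum, np.empty(0, dtype=np.intp))
        if len(avail) < n:
            raise ParameterError(
                f"control pool exhausted for stratum {stratum!r}: need {n}, have {len(avail)}"
            )
        ctrl_parts.append(rng.choice(avail, size=n, replace=False))
    ctrl_idx = np.sort(np.concatenate(ctrl_parts))
    X = np.vstack([bm_m6a.bound[pos_idx], bm_pool.bound[ctrl_idx]]).astype(np.int8)
    y = np.concatenate([np.ones(len(pos_idx), dtype=int), np.zeros(len(ctrl_idx), dtype=int)])
    return X, y


def train_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    cfg: ClassifierConfig,
    control_set_id: int = 0,
) -> ClassifierRun:
    """Fit and evaluate the forest for one control-set dataset.

    The data is split 80:20 stratified by label; 5-fold CV accuracy is
    measured inside the training portion (model validation), then the forest
    is refit on the full training portion and scored on the untouched test
    split (confusion counts, accuracy, AUROC, ROC curve). Importance is
    impurity-based and normalised to sum 1.
    """
    if len(y) < 2 * cfg.cv_folds:
        raise ParameterError("dataset smaller than 2 x cv_folds")
    mtry = default_mtry(X.shape[1]) if cfg.mtry == "sqrt" else int(cfg.mtry)
    if mtry > X.shape[1]:
        raise ParameterError(f"mtry={mtry} exceeds n_features={X.shape[1]}")
    split_seed = np.random.SeedSequence([cfg.seed, control_set_id]).generate_state(3)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=cfg.train_frac, stratify=y,
        random_state=int(split_seed[0] % (2**31)),
    )
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        random_state=int(split_seed[1] % (2**31)),
        n_jobs=1,
    )
    cv = StratifiedKFold(
        n_splits=cfg.cv_folds, shuffle=True, random_state=int(split_seed[2] % (2**31))
    )
    cv_accuracy = float(cross_val_score(rf, X_tr, y_tr, cv=cv, scoring="accuracy").mean())
    rf.fit(X_tr, y_tr)
    y_hat = rf.predict(X_te)
    scores = rf.predict_proba(X_te)[:, 1]
    tn, fp, fn, tp = confusion_matrix(y_te, y_hat, labels=[0, 1]).ravel()
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    fpr, tpr, _ = roc_curve(y_te, scores)
    return ClassifierRun(
        control_set_id=control_set_id,
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        accuracy=accuracy(int(tp), int(tn), int(fp), int(fn)),
        cv_accuracy=cv_accuracy,
        auroc=auroc(scores, y_te),
        importance=dict(zip(feature_names, imp.tolist())),
        fpr=fpr,
        tpr=tpr,
    )


def run_control_sets(
    bm_m6a: BindingMatrix,
    bm_pool: BindingMatrix,
    pool: ControlPool,
    cfg: ClassifierConfig,
) -> list[ClassifierRun]:
    """Repeat build_dataset + train_evaluate over cfg.n_control_sets draws."""
    runs = []
    for cid in range(cfg.n_control_sets):
        X, y = build_dataset(bm_m6a, bm_pool, pool, control_set_id=cid, seed=cfg.seed)
        runs.append(train_evaluate(X, y, list(bm_m6a.rbps), cfg, control_set_id=cid))
        logger.info(
            "control set %d: accuracy=%.3f auroc=%.3f", cid,
            runs[-1].accuracy, runs[-1].auroc,
        )
    return runs


@dataclass
class ClassifierSummary:
    mean_accuracy: float
    mean_cv_accuracy: float
    mean_auroc: float
    mean_importance: pd.Series
    top_features: list[str]
    roc_grid: pd.DataFrame  # columns fpr, mean_tpr


def aggregate_runs(
    runs: Sequence[ClassifierRun], top_k: int = 10, grid_points: int = 101
) -> ClassifierSummary:
    """Average metrics across control sets; ROC averaged vertically on a fixed
    false-positive-rate grid; top_k features ranked by mean importance."""
    if not runs:
        raise ParameterError("aggregate_runs needs at least one run")
    imp = pd.DataFrame([dict(r.importance) for r in runs]).fillna(0.0)
    mean_imp = imp.mean(axis=0).sort_values(ascending=False, kind="stable")
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = [np.interp(grid, r.fpr, r.tpr) for r in runs]
    roc = pd.DataFrame({"fpr": grid, "mean_tpr": np.mean(tprs, axis=0)})
    return ClassifierSummary(
        mean_accuracy=float(np.mean([r.accuracy for r in runs])),
        mean_cv_accuracy=float(np.mean([r.cv_accuracy for r in runs])),
        mean_auroc=float(np.mean([r.auroc for r in runs])),
        mean_importance=mean_imp,
        top_features=mean_imp.index[:top_k].tolist(),
        roc_grid=roc,
    )
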