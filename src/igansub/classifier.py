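"""Single-sample random-forest subtype classifier.

The protocol: features are the case-vs-control DEG set, samples are the
consensus-voted cases, split 3:1 stratified by subtype, (mtry, ntree)
chosen on a grid by out-of-bag error, evaluated on the held-out quarter by
accuracy and one-vs-rest ROC AUC from class-vote fractions, and validated
by stratified 5-fold cross-validation with per-fold retuning.  "Single
sample" means prediction needs only one sample's expression vector over
the stored feature list.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class ForestModel:
    """A fitted forest plus the feature list and label order it expects."""

    forest: RandomForestClassifier
    features: List[str]
    classes: List[int]
    mtry: int
    ntree: int
    oob_error: float


@dataclass
class ClassifierReport:
    accuracy: float
    per_class_auc: Dict[int, float]
    macro_auc: float
    oob_error: float | None = None
    cv_accuracy: float | None = None
    chosen_mtry: int | None = None
    chosen_ntree: int | None = None


def default_grids(n_features: int) -> Tuple[List[int], List[int]]:
    """mtry in {sqrt(p), p/10, p/5, 9}, ntree in {100..500 step 100}."""
    mtry = sorted({max(1, int(round(math.sqrt(n_features)))),
                   max(1, n_features // 10),
                   max(1, n_features // 5),
                   9})
    return mtry, [100, 200, 300, 400, 500]


def split_train_test(sample_ids: Sequence[str], labels: Sequence[int],
                     ratio: float = 0.75, seed: int = 0,
                     ) -> Tuple[List[str], List[str]]:
    """Stratified train/test split (default 3:1), deterministic given seed.

    Per class, round(ratio * n) samples go to training with at least one
    sample kept on each side.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    ids = np.asarray(list(sample_ids))
    labs = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    train: List[str] = []
    test: List[str] = []
    for lab in np.unique(labs):
        members = ids[labs == lab]
        if len(members) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 members")
        n_train = int(math.floor(ratio * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train.extend(members[perm[:n_train]])
        test.extend(members[perm[n_train:]])
    return train, test


def _fit_forest(X: np.ndarray, y: np.ndarray, mtry: int, ntree: int,
                seed: int) -> RandomForestClassifier:
    rf = RandomForestClassifier(n_estimators=ntree, max_features=mtry,
                                oob_score=True, bootstrap=True,
                                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse-OOB warnings on tiny grids
        rf.fit(X, y)
    return rf


def tune_forest(expr_train: pd.DataFrame, labels: Sequence[int],
                mtry_grid: Sequence[int] | None = None,
                ntree_grid: Sequence[int] | None = None,
                seed: int = 0) -> ForestModel:
    """Grid-search (mtry, ntree) by OOB error on the training samples.

    ``expr_train`` is genes x samples over the DEG feature set.  Ties are
    broken toward smaller ntree, then smaller mtry.  Grid points with
    mtry > feature count are skipped with a warning.
    """
    X = expr_train.to_numpy(float).T
    y = np.asarray(list(labels), dtype=int)
    p = X.shape[1]
    if mtry_grid is None or ntree_grid is None:
        d_mtry, d_ntree = default_grids(p)
        mtry_grid = list(mtry_grid) if mtry_grid is not None else d_mtry
        ntree_grid = list(ntree_grid) if ntree_grid is not None else d_ntree
    if not mtry_grid or not ntree_grid:
        raise ValueError("grids must be nonempty")

    best: Tuple[float, int, int] | None = None
    for ntree in sorted(ntree_grid):
        for mtry in sorted(mtry_grid):
            if mtry > p:
                log.warning("tune_forest: skipping mtry=%d > %d features",
                            mtry, p)
                continue
            rf = _fit_forest(X, y, mtry, ntree, seed)
            err = 1.0 - float(rf.oob_score_)
            if best is None or err < best[0] - 1e-12:
                best = (err, ntree, mtry)
    if best is None:
        raise ValueError("no admissible grid point")
    err, ntree, mtry = best
    rf = _fit_forest(X, y, mtry, ntree, seed)
    return ForestModel(forest=rf, features=list(expr_train.index),
                       classes=[int(c) for c in rf.classes_],
                       mtry=mtry, ntree=ntree, oob_error=err)


def predict_samples(model: ForestModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample predicted subtype and class-vote fractions.

    Each prediction uses one sample's expression vector over the model's
    stored feature list (the single-sample contract).
    """
    missing = [f for f in model.features if f not in expr.index]
    if missing:
        raise KeyError(f"expression matrix lacks model features: {missing[:5]}")
    X = expr.loc[model.features].to_numpy(float).T
    proba = model.forest.predict_proba(X)
    pred = model.forest.classes_[np.argmax(proba, axis=1)]
    out = pd.DataFrame(proba, index=expr.columns,
                       columns=[f"vote_{c}" for c in model.classes])
    out.insert(0, "predicted", pred.astype(int))
    return out


def evaluate(model: ForestModel, expr_test: pd.DataFrame,
             labels: Sequence[int]) -> ClassifierReport:
    """Accuracy plus one-vs-rest AUCs from vote fractions on held-out data.

    AUC uses the Mann-Whitney convention (score ties contribute 1/2).  A
    class absent from the test set has no defined AUC; the macro average
    runs over defined classes with a warning.
    """
    y = np.asarray(list(labels), dtype=int)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = predict_samples(model, expr_test)
    accuracy = float((pred["predicted"].to_numpy() == y).mean())
    aucs: Dict[int, float] = {}
    for j, c in enumerate(model.classes):
        pos = y == c
        if pos.all() or not pos.any():
            log.warning("evaluate: class %s one-sided in test set; AUC skipped", c)
            continue
        scores = pred[f"vote_{c}"].to_numpy(float)
        aucs[c] = _mann_whitney_auc(scores[pos], scores[~pos])
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return ClassifierReport(accuracy=accuracy, per_class_auc=aucs,
                            macro_auc=macro, oob_error=model.oob_error,
                            chosen_mtry=model.mtry, chosen_ntree=model.ntree)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = U / (n_pos * n_neg) with the tie-midrank convention."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def cross_validate(expr: pd.DataFrame, labels: Sequence[int],
                   folds: int = 5, seed: int = 0,
                   mtry_grid: Sequence[int] | None = None,
                   ntree_grid: Sequence[int] | None = None) -> float:
    """Mean held-out accuracy over stratified folds with per-fold retuning."""
    y = np.asarray(list(labels), dtype=int)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError("every class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X_cols = np.asarray(expr.columns)
    accs = []
    for tr, te in skf.split(X_cols, y):
        model = tune_forest(expr[X_cols[tr]], y[tr], mtry_grid=mtry_grid,
                            ntree_grid=ntree_grid, seed=seed)
        rep = evaluate(model, expr[X_cols[te]], y[te])
        accs.append(rep.accuracy)
    return float(np.mean(accs))
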