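"""Per-feature predictive ranking by cross-validated SVM, and top-k
ROC/AUC stability curves.

Each feature is scored on its own: within a stratified 5-fold split, the
training half is median-imputed and standardized, a linear max-margin
classifier (SVM, C = 1) is fitted on the single feature, and the held-out
accuracy is recorded; the score is the mean over folds. Higher score means
better single-feature predictive ability. Ties are broken by feature name so
a ranking is a deterministic function of (table, labels, cv_seed).

The stability curve refits the same classifier on the top-k features for a
grid of k, pools held-out decision scores over folds into one ROC curve, and
reports the trapezoidal AUC per k — the curve flattens once the informative
features are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import FeatureTable

__all__ = [
    "RankedFeature",
    "StabilityCurve",
    "rank_features",
    "stability_curve",
    "prune_correlated",
]

N_FOLDS = 5


@dataclass
class RankedFeature:
    name: str
    score: float  # mean held-out accuracy over folds, in [0, 1]
    rank: int  # 1 = best
    fold_scores: tuple[float, ...]
    constant: bool = False  # flagged: feature had no spread, score 0.5 by convention


@dataclass
class StabilityCurve:
    k_values: tuple[int, ...]
    auc_at_k: tuple[float, ...]
    roc_points: dict[int, np.ndarray]  # k -> (n_points, 2) array of (fpr, tpr)


def _check_labels(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"labels must be binary with both classes present, got {classes}"
        )
    return (y == classes.max()).astype(int)


def _prep_fold(col: np.ndarray, train: np.ndarray, test: np.ndarray):
    """Median-impute and standardize a feature column using training data only."""
    tr = col[train].copy()
    te = col[test].copy()
    med = np.nanmedian(tr)
    if np.isnan(med):
        return None  # all-missing in this training fold
    tr[np.isnan(tr)] = med
    te[np.isnan(te)] = med
    mu, sd = tr.mean(), tr.std()
    if sd == 0:
        return None  # constant in this training fold
    return (tr - mu) / sd, (te - mu) / sd


def rank_features(
    table: FeatureTable, labels, cv_seed: int = 0
) -> list[RankedFeature]:
    """Rank every feature by mean held-out accuracy of a single-feature SVM.

    Parameters
    ----------
    table : FeatureTable
    labels : array-like aligned with ``table.ids``, binary.
    cv_seed : int
        Seed of the stratified 5-fold shuffle; fixes the ranking bitwise.
    """
    y = _check_labels(np.asarray(pd.Series(labels).to_numpy()))
    X = table.data.to_numpy(dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match table rows")
    counts = np.bincount(y)
    if counts.min() < N_FOLDS:
        raise ValueError(
            f"need >= {N_FOLDS} samples per class for {N_FOLDS}-fold CV, "
            f"got class counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=cv_seed)
    folds = list(skf.split(X, y))

    results = []
    for ci, name in enumerate(table.names):
        col = X[:, ci]
        fold_scores = []
        degenerate = False
        for train, test in folds:
            prepped = _prep_fold(col, train, test)
            if prepped is None:
                fold_scores.append(0.5)
                degenerate = True
                continue
            xtr, xte = prepped
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(xtr[:, None], y[train])
            fold_scores.append(float(np.mean(clf.predict(xte[:, None]) == y[test])))
        results.append((name, float(np.mean(fold_scores)), tuple(fold_scores),
                        degenerate))

    # sort: score descending, name ascending (deterministic tie-break)
    results.sort(key=lambda t: (-t[1], t[0]))
    return [
        RankedFeature(name=n, score=s, rank=i + 1, fold_scores=fs, constant=dg)
        for i, (n, s, fs, dg) in enumerate(results)
    ]


def stability_curve(
    table: FeatureTable,
    labels,
    ranking: list[RankedFeature],
    k_grid,
    cv_seed: int = 0,
) -> StabilityCurve:
    """Pooled held-out ROC/AUC of the top-k feature SVM for each k in k_grid."""
    y = _check_labels(np.asarray(pd.Series(labels).to_numpy()))
    p = len(ranking)
    k_grid = [int(k) for k in k_grid]
    if any(k < 1 or k > p for k in k_grid):
        raise ValueError(f"k values must lie in 1..{p}, got {k_grid}")
    ordered = [rf.name for rf in sorted(ranking, key=lambda r: r.rank)]
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=cv_seed)
    X_all = table.data
    folds = list(skf.split(X_all.to_numpy(), y))

    aucs, rocs = [], {}
    for k in k_grid:
        X = X_all[ordered[:k]].to_numpy(dtype=float)
        scores = np.empty(len(y))
        for train, test in folds:
            cols_tr, cols_te = [], []
            for ci in range(k):
                prepped = _prep_fold(X[:, ci], train, test)
                if prepped is None:
                    cols_tr.append(np.zeros(len(train)))
                    cols_te.append(np.zeros(len(test)))
                else:
                    cols_tr.append(prepped[0])
                    cols_te.append(prepped[1])
            xtr = np.column_stack(cols_tr)
            xte = np.column_stack(cols_te)
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(xtr, y[train])
            scores[test] = clf.decision_function(xte)
        fpr, tpr, _ = roc_curve(y, scores)
        aucs.append(float(np.trapezoid(tpr, fpr)))
        rocs[k] = np.column_stack([fpr, tpr])
    return StabilityCurve(tuple(k_grid), tuple(aucs), rocs)


def prune_correlated(table: FeatureTable, threshold: float = 0.95) -> list[str]:
    """Optional independence filter: greedily drop features whose absolute
    Pearson correlation with an already-kept feature exceeds ``threshold``.

    Returns the kept feature names in original column order.
    """
    corr = table.data.corr().abs().to_numpy()
    names = table.names
    kept: list[int] = []
    for i in range(len(names)):
        if all(not (corr[i, j] > threshold) for j in kept):
            kept.append(i)
    return [names[i] for i in kept]
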