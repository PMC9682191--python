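"""Cross-validated evaluation of feature selections.

Stratified 10-fold cross-validation with a per-fold pipeline: fit the
selector on the training rows only (anchor graphs and feature scaling
included), take the top-scoring features, train a linear max-margin
classifier on the reduced training block, and report accuracy, sensitivity,
specificity, and AUC on the held-out fold.  Nothing from the test fold
touches graph construction, scaling, fitting, or selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .data import MultiModalDataset
from .errors import ValidationError
from .optim import Hyperparams, fit
from .selection import rank_features

__all__ = [
    "FoldMetrics",
    "CVResult",
    "stratified_kfold",
    "binary_metrics",
    "cross_validate",
    "grid_search",
]


@dataclass
class FoldMetrics:
    acc: float
    sen: float
    spe: float
    auc: float


@dataclass
class CVResult:
    """Per-fold metrics with summary statistics and provenance."""

    per_fold: list[FoldMetrics]
    means: dict[str, float]
    stds: dict[str, float]
    selected_per_fold: list[list[int]]
    config: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


def stratified_kfold(
    labels: np.ndarray, n_folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-balanced fold split; deterministic given seed.

    Every class must have at least ``n_folds`` members; per-class counts
    across test folds differ by at most 1.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = counts < n_folds
    if small.any():
        bad = classes[small][0]
        raise ValidationError(
            f"class {bad!r} has fewer than n_folds={n_folds} members"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dummy = np.zeros_like(labels, dtype=float)
    return [
        (train.copy(), test.copy()) for train, test in skf.split(dummy, labels)
    ]


def binary_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> FoldMetrics:
    """Accuracy, sensitivity, specificity, AUC for binary predictions.

    Positive class is label 1.  sen = TP/(TP+FN), spe = TN/(TN+FP); AUC is
    the Mann-Whitney rank statistic of the scores (ties counted 1/2).  When
    ``y_true`` contains a single class the undefined metrics are returned as
    NaN (flagged missing), never as 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValidationError("y_true, y_pred, y_score lengths must match")
    acc = float(np.mean(y_true == y_pred))
    pos = y_true == 1
    neg = y_true == 0
    sen = float(np.mean(y_pred[pos] == 1)) if pos.any() else math.nan
    spe = float(np.mean(y_pred[neg] == 0)) if neg.any() else math.nan
    if pos.any() and neg.any():
        # Mann-Whitney with midranks: P(score_pos > score_neg) + 0.5 ties
        from scipy.stats import rankdata

        ranks = rankdata(y_score)
        n_pos, n_neg = int(pos.sum()), int(neg.sum())
        auc = float(
            (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        )
    else:
        auc = math.nan
    return FoldMetrics(acc=acc, sen=sen, spe=spe, auc=auc)


def _summarize(per_fold: list[FoldMetrics]) -> tuple[dict, dict]:
    means, stds = {}, {}
    for name in ("acc", "sen", "spe", "auc"):
        vals = np.array([getattr(f, name) for f in per_fold], dtype=float)
        vals = vals[~np.isnan(vals)]
        means[name] = float(vals.mean()) if vals.size else math.nan
        stds[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return means, stds


def make_classifier():
    """Default downstream classifier: scaled linear max-margin (SVM)."""
    return make_pipeline(StandardScaler(), LinearSVC())


def cross_validate(
    data: MultiModalDataset,
    hp: Hyperparams | None = None,
    n_select: int | None = 20,
    n_folds: int = 10,
    seed: int = 0,
    classifier_factory=make_classifier,
    score_mode: str = "theta_weighted",
) -> CVResult:
    """Per-fold fit -> select -> classify, leakage-free.

    ``n_select=None`` keeps all features (selector acts as a pure ranker).
    """
    hp = Hyperparams() if hp is None else hp
    if data.n_classes != 2:
        raise ValidationError("cross_validate supports binary labels only")
    labels = data.labels
    folds = stratified_kfold(labels, n_folds, seed=seed)
    per_fold: list[FoldMetrics] = []
    selected_sets: list[list[int]] = []
    X_full = data.concatenated()
    for train_idx, test_idx in folds:
        train = data.subset(train_idx)
        state = fit(train, hp)
        k = train.total_dim if n_select is None else n_select
        ranking = rank_features(state, n_select=k, mode=score_mode)
        idx = ranking.selected
        selected_sets.append(idx)
        clf = classifier_factory()
        clf.fit(X_full[train_idx][:, idx], labels[train_idx])
        y_pred = clf.predict(X_full[test_idx][:, idx])
        y_score = clf.decision_function(X_full[test_idx][:, idx])
        per_fold.append(binary_metrics(labels[test_idx], y_pred, y_score))
    means, stds = _summarize(per_fold)
    return CVResult(
        per_fold=per_fold,
        means=means,
        stds=stds,
        selected_per_fold=selected_sets,
        config={
            "n_select": n_select,
            "n_folds": n_folds,
            "seed": seed,
            "hyperparams": asdict(hp),
        },
    )


def grid_search(
    data: MultiModalDataset,
    alpha_grid,
    beta_grid,
    n_select: int | None = 20,
    n_folds: int = 10,
    seed: int = 0,
    hp: Hyperparams | None = None,
) -> pd.DataFrame:
    """Parameter-sensitivity sweep: one CV summary row per (alpha, beta).

    Returns a tidy table with mean and standard deviation of each metric.
    The harness reports the whole grid; it never picks the test-best cell.
    """
    alpha_grid = list(alpha_grid)
    beta_grid = list(beta_grid)
    if not alpha_grid or not beta_grid:
        raise ValidationError("grids must be nonempty")
    base = Hyperparams() if hp is None else hp
    rows = []
    from dataclasses import replace

    for alpha in alpha_grid:
        for beta in beta_grid:
            cell_hp = replace(base, alpha=alpha, beta=beta)
            res = cross_validate(
                data, cell_hp, n_select=n_select, n_folds=n_folds, seed=seed
            )
            row = {"alpha": alpha, "beta": beta, "n_select": n_select}
            for name in ("acc", "sen", "spe", "auc"):
                row[f"{name}_mean"] = res.means[name]
                row[f"{name}_sd"] = res.stds[name]
            rows.append(row)
    return pd.DataFrame(rows)
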