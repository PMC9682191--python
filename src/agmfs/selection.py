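"""Turning a fitted model into feature scores, subsets, and modality weights.

Two learned quantities carry importance information: the row norms of the
weight matrices (a feature with an all-zero row contributes nothing to the
prediction) and the simplex vector theta (a learned nonnegative weight per
feature, summing to 1 across all modalities).  The default score multiplies
them; the plain row norm is kept for ablation.  Modality importance is the
within-modality sum of theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .optim import ModelState

__all__ = [
    "FeatureRanking",
    "feature_scores",
    "select_top_k",
    "modality_importance",
    "rank_features",
]


@dataclass
class FeatureRanking:
    """Per-feature scores plus the derived subset and modality summary."""

    scores: np.ndarray
    order: np.ndarray
    selected: list[int]
    modality_importance: np.ndarray
    mode: str
    n_select: int


def feature_scores(state: ModelState, mode: str = "theta_weighted") -> np.ndarray:
    """Nonnegative importance per feature (concatenated across modalities).

    ``row_norm``: l2 norm of each row of the stacked weight matrix.
    ``theta_weighted`` (default): that row norm multiplied by the feature's
    simplex weight theta_i.
    """
    if not state.fitted:
        raise ValidationError("feature_scores requires a fitted ModelState")
    W = np.vstack(state.W)
    norms = np.sqrt(np.sum(W * W, axis=1))
    if mode == "row_norm":
        return norms
    if mode == "theta_weighted":
        return state.theta * norms
    raise ValidationError(f"unknown scoring mode: {mode!r}")


def select_top_k(scores: np.ndarray, n_select: int) -> list[int]:
    """Indices of the n_select largest scores; ties favor the smaller index."""
    scores = np.asarray(scores, dtype=float)
    d = scores.shape[0]
    if not 1 <= n_select <= d:
        raise ValidationError(f"n_select={n_select} out of range 1..{d}")
    # stable sort on -scores: equal scores keep ascending index order
    order = np.argsort(-scores, kind="stable")
    return sorted(order[:n_select].tolist())


def modality_importance(theta: np.ndarray, dims: list[int]) -> np.ndarray:
    """Within-modality sums of theta; entries sum to 1 like theta itself."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != sum(dims):
        raise ValidationError(
            f"theta length {theta.shape[0]} does not match dims sum {sum(dims)}"
        )
    out, start = [], 0
    for d in dims:
        out.append(float(theta[start : start + d].sum()))
        start += d
    return np.array(out)


def rank_features(
    state: ModelState,
    n_select: int | None = None,
    mode: str = "theta_weighted",
) -> FeatureRanking:
    """Full ranking report for a fitted model."""
    scores = feature_scores(state, mode=mode)
    d = scores.shape[0]
    if n_select is None:
        n_select = d
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        scores=scores,
        order=order,
        selected=select_top_k(scores, n_select),
        modality_importance=modality_importance(state.theta, state.dims),
        mode=mode,
        n_select=n_select,
    )
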