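"""Anchor graphs: sparse sample-to-anchor affinities replacing dense graphs.

Instead of an ``n x n`` similarity matrix, a small set of ``m`` anchor points
is chosen per modality and each sample is connected to its ``k`` nearest
anchors with closed-form weights.  The implied sample similarity
``S = Z Delta^{-1} Z^T`` (with ``Delta_jj = sum_i z_ij``) is row-stochastic,
so its graph Laplacian is simply ``L = I - B B^T`` with
``B = Z Delta^{-1/2}`` — and every Laplacian quadratic form can be computed
from ``B`` in ``O(n m c)`` without ever materializing ``S``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorGraph",
    "select_anchors",
    "compute_Z",
    "compute_B",
    "similarity",
    "laplacian_quadratic",
    "build_anchor_graph",
    "default_n_anchors",
]


@dataclass
class AnchorGraph:
    """Anchors plus the k-sparse row-stochastic affinity and its factor B.

    Attributes
    ----------
    anchors:
        ``(m, d)`` anchor coordinates.
    Z:
        ``(n, m)`` nonnegative affinity; each row sums to 1 and has at most
        ``k_nn`` nonzeros.
    delta:
        Column sums of ``Z`` (diagonal of the anchor-degree matrix); strictly
        positive because zero-mass anchors are dropped before ``B`` is formed.
    B:
        ``Z @ diag(delta)^{-1/2}``; ``B B^T`` is the row-stochastic sample
        similarity.
    """

    anchors: np.ndarray
    Z: np.ndarray
    delta: np.ndarray
    B: np.ndarray
    k_nn: int

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    @property
    def n(self) -> int:
        return self.Z.shape[0]


def default_n_anchors(n: int) -> int:
    """Default anchor count: ``min(4 * ceil(sqrt(n)), n)``."""
    return int(min(4 * np.ceil(np.sqrt(n)), n))


def select_anchors(
    X: np.ndarray,
    m: int,
    strategy: str = "random",
    seed: int = 0,
) -> np.ndarray:
    """Pick ``m`` anchor points from the rows of ``X``.

    ``random`` samples rows uniformly without replacement (O(1) per anchor);
    ``kmeans`` uses k-means centroids instead, trading speed for coverage.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if m < 1:
        raise ValidationError("anchor count m must be at least 1")
    if m > n:
        raise ValidationError(f"anchor count m={m} exceeds sample count n={n}")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=m, replace=False)
        return X[np.sort(idx)].copy()
    if strategy == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=m, n_init=4, random_state=seed)
        km.fit(X)
        return km.cluster_centers_.astype(float)
    raise ValidationError(f"unknown anchor strategy: {strategy!r}")


def compute_Z(X: np.ndarray, anchors: np.ndarray, k_nn: int) -> np.ndarray:
    """Closed-form k-sparse affinities from squared Euclidean distances.

    For each sample, with anchor distances sorted ascending
    ``d_1 <= ... <= d_m``, the k nearest anchors receive
    ``z_j = (d_{k+1} - d_j) / (k d_{k+1} - sum_{l<=k} d_l)`` and all others 0.
    Rows sum to 1 exactly (up to roundoff).  The row-wise regularization
    weight of the underlying quadratic graph-learning problem is absorbed
    into this closed form via the (k+1)-th neighbor distance, so the only
    parameter is ``k_nn``.

    Degenerate rows whose k+1 nearest distances are all equal (zero
    denominator) fall back to uniform ``1/k`` weights over the k nearest
    anchors, with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    anchors = np.asarray(anchors, dtype=float)
    n, m = X.shape[0], anchors.shape[0]
    if not 1 <= k_nn <= m - 1:
        raise ValidationError(
            f"k_nn={k_nn} must satisfy 1 <= k_nn <= m-1 (m={m} anchors)"
        )
    D = cdist(X, anchors, metric="sqeuclidean")
    # stable sort: distance ties broken by anchor index
    order = np.argsort(D, axis=1, kind="stable")
    sorted_D = np.take_along_axis(D, order, axis=1)
    d_kplus1 = sorted_D[:, k_nn]
    top = sorted_D[:, :k_nn]
    denom = k_nn * d_kplus1 - top.sum(axis=1)

    weights = d_kplus1[:, None] - top
    degenerate = denom <= 1e-300
    n_degen = int(degenerate.sum())
    if n_degen:
        logger.warning(
            "compute_Z: %d degenerate row(s) with equal k+1 nearest distances; "
            "using uniform 1/k weights",
            n_degen,
        )
        weights[degenerate] = 1.0
        denom[degenerate] = float(k_nn)
    weights = weights / denom[:, None]

    Z = np.zeros((n, m))
    np.put_along_axis(Z, order[:, :k_nn], weights, axis=1)
    return Z


def compute_B(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree-normalize: ``delta_j = sum_i z_ij``, ``B = Z diag(delta)^{-1/2}``.

    Anchors that receive no mass (zero columns) are dropped from both ``Z``
    and ``B`` with a logged warning; an all-zero ``Z`` is an error.
    """
    Z = np.asarray(Z, dtype=float)
    delta = Z.sum(axis=0)
    keep = delta > 0
    if not keep.any():
        raise ValidationError("Z has no mass: every anchor column sums to 0")
    if not keep.all():
        logger.warning(
            "compute_B: dropping %d zero-mass anchor column(s)",
            int((~keep).sum()),
        )
        Z = Z[:, keep]
        delta = delta[keep]
    B = Z / np.sqrt(delta)[None, :]
    return B, delta


def similarity(Z: np.ndarray, max_n: int = 2000) -> np.ndarray:
    """Materialize the implied sample similarity ``S = Z Delta^{-1} Z^T``.

    Only intended for small ``n`` (inspection, testing); above ``max_n`` an
    error directs the caller to :func:`laplacian_quadratic`, which never
    forms ``S``.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n > max_n:
        raise ValidationError(
            f"n={n} exceeds the materialization cap {max_n}; "
            "use laplacian_quadratic on B instead of forming S"
        )
    B, _ = compute_B(Z)
    return B @ B.T


def laplacian_quadratic(B: np.ndarray, M: np.ndarray) -> float:
    """``tr(M^T (I - B B^T) M)`` in O(nmc), via ``||M||_F^2 - ||B^T M||_F^2``.

    Nonnegative up to roundoff: ``B B^T`` is symmetric row-stochastic, so
    ``I - B B^T`` is positive semidefinite.
    """
    B = np.asarray(B, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if B.shape[0] != M.shape[0]:
        raise ValidationError(
            f"row mismatch: B has {B.shape[0]} rows, M has {M.shape[0]}"
        )
    return float(np.sum(M * M) - np.sum((B.T @ M) ** 2))


def build_anchor_graph(
    X: np.ndarray,
    m: int | None = None,
    k_nn: int = 5,
    strategy: str = "random",
    seed: int = 0,
) -> AnchorGraph:
    """Convenience: anchors -> Z -> B for one modality's feature matrix."""
    X = np.asarray(X, dtype=float)
    if m is None:
        m = default_n_anchors(X.shape[0])
    anchors = select_anchors(X, m, strategy=strategy, seed=seed)
    Z = compute_Z(X, anchors, k_nn)
    B, delta = compute_B(Z)
    if B.shape[1] != Z.shape[1]:
        Z = Z[:, Z.sum(axis=0) > 0]
    return AnchorGraph(anchors=anchors, Z=Z, delta=delta, B=B, k_nn=k_nn)
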