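"""In-memory container for multi-modal feature tables.

A multi-modal dataset is a list of per-modality matrices ``X_v`` of shape
``(n_samples, d_v)`` that share a common row (sample) order, together with a
one-hot label matrix ``Y`` of shape ``(n_classes, n_samples)``.  The one-hot
layout (classes along rows) matches the least-squares regression target used
by the fitting objective, where predictions ``W^T Theta X^T`` are compared to
``Y`` column by column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["MultiModalDataset", "one_hot"]


def one_hot(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Encode integer class labels as a ``(n_classes, n)`` {0,1} matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValidationError("labels must be a 1-D integer vector")
    k = int(labels.max()) + 1 if n_classes is None else int(n_classes)
    if labels.min() < 0 or labels.max() >= k:
        raise ValidationError(f"labels out of range for {k} classes")
    Y = np.zeros((k, labels.size))
    Y[labels, np.arange(labels.size)] = 1.0
    return Y


@dataclass
class MultiModalDataset:
    """Per-modality feature blocks sharing row order, plus one-hot labels.

    Parameters
    ----------
    blocks:
        List of ``(n, d_v)`` float arrays, one per modality, rows aligned.
    Y:
        ``(k, n)`` one-hot label matrix with unit column sums.
    modality_names:
        Optional names, default ``mod1..modV``.
    sample_ids:
        Optional per-row identifiers (kept through I/O round-trips).
    class_order:
        Original label values in the order used for one-hot rows.
    """

    blocks: list[np.ndarray]
    Y: np.ndarray
    modality_names: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None
    class_order: list | None = None

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        self.Y = np.asarray(self.Y, dtype=float)
        if not self.blocks:
            raise ValidationError("dataset needs at least one modality block")
        n = self.blocks[0].shape[0]
        for i, b in enumerate(self.blocks):
            if b.ndim != 2:
                raise ValidationError(f"block {i} is not a 2-D matrix")
            if b.shape[0] != n:
                raise ValidationError(
                    f"block {i} has {b.shape[0]} rows, expected {n}"
                )
        if self.Y.ndim != 2 or self.Y.shape[1] != n:
            raise ValidationError(f"Y must have shape (k, {n})")
        col_sums = self.Y.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValidationError("Y columns must each sum to 1 (one-hot)")
        if not self.modality_names:
            self.modality_names = [f"mod{i + 1}" for i in range(len(self.blocks))]
        if len(self.modality_names) != len(self.blocks):
            raise ValidationError("modality_names length must match blocks")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValidationError("sample_ids length must match row count")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_classes(self) -> int:
        return self.Y.shape[0]

    @property
    def dims(self) -> list[int]:
        return [b.shape[1] for b in self.blocks]

    @property
    def total_dim(self) -> int:
        return int(sum(self.dims))

    @property
    def labels(self) -> np.ndarray:
        """Integer class index per sample (argmax of the one-hot columns)."""
        return np.argmax(self.Y, axis=0)

    def concatenated(self) -> np.ndarray:
        """Column-concatenation of all modality blocks, shape ``(n, d)``."""
        return np.concatenate(self.blocks, axis=1)

    def subset(self, indices) -> "MultiModalDataset":
        """Row-subset (e.g. a CV fold), preserving block structure."""
        indices = np.asarray(indices, dtype=int)
        return MultiModalDataset(
            blocks=[b[indices] for b in self.blocks],
            Y=self.Y[:, indices],
            modality_names=list(self.modality_names),
            sample_ids=None
            if self.sample_ids is None
            else [self.sample_ids[i] for i in indices],
            class_order=self.class_order,
        )

    def segment_slices(self) -> list[slice]:
        """Slices of the concatenated feature axis, one per modality."""
        out, start = [], 0
        for d in self.dims:
            out.append(slice(start, start + d))
            start += d
        return out
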