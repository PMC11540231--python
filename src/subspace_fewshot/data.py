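"""Feature-table container shared by every stage of the pipeline.

A :class:`FeatureDataset` holds one row per image: an ``N x M`` matrix of
real-valued features (typically penultimate-layer activations of a deep
network, M = 512 for ResNet-18) together with integer class labels in
``0..C-1``.  All downstream statistics (scatter matrices, subspaces,
episodes) are computed from this container, so validation happens once,
here, up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureDataset", "ValidationError", "MAX_FEATURES_DEFAULT"]

#: Cap on the feature dimension M.  Scatter matrices are stored dense
#: (M x M); the intended regime is M around 512, and the cap keeps an
#: accidental huge allocation an explicit choice rather than a surprise.
MAX_FEATURES_DEFAULT = 4096


class ValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass(frozen=True)
class FeatureDataset:
    """N samples in M feature dimensions with class labels in ``0..C-1``.

    Parameters
    ----------
    features:
        ``(N, M)`` float array; every entry must be finite.
    labels:
        ``(N,)`` integer array of class indices ``0..C-1``.  Every class
        index below the maximum must occur at least once.
    ids:
        Optional per-row identifiers (defaults to ``"0".."N-1"``).
    """

    features: np.ndarray
    labels: np.ndarray
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.float64)
        labels = np.asarray(self.labels)
        if feats.ndim != 2:
            raise ValidationError(f"features must be 2-D, got shape {feats.shape}")
        if feats.shape[0] == 0:
            raise ValidationError("feature table has zero rows")
        if feats.shape[1] == 0:
            raise ValidationError("feature table has zero feature columns")
        if feats.shape[1] > MAX_FEATURES_DEFAULT:
            raise ValidationError(
                f"M={feats.shape[1]} exceeds the dense-scatter cap "
                f"({MAX_FEATURES_DEFAULT})"
            )
        if not np.all(np.isfinite(feats)):
            raise ValidationError("features contain non-finite entries (NaN/Inf)")
        if labels.ndim != 1 or labels.shape[0] != feats.shape[0]:
            raise ValidationError(
                f"labels must be a length-{feats.shape[0]} vector, got shape "
                f"{labels.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == labels.astype(np.int64)):
                raise ValidationError("labels must be integers")
        labels = labels.astype(np.int64)
        if labels.min() < 0:
            raise ValidationError("labels must be non-negative class indices")
        c = int(labels.max()) + 1
        counts = np.bincount(labels, minlength=c)
        missing = np.nonzero(counts == 0)[0]
        if missing.size:
            raise ValidationError(
                f"class index {int(missing[0])} has no samples (labels must "
                f"cover 0..C-1 contiguously)"
            )
        ids = self.ids if self.ids else tuple(str(i) for i in range(feats.shape[0]))
        if len(ids) != feats.shape[0]:
            raise ValidationError("ids length does not match number of rows")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", tuple(str(i) for i in ids))

    # -- shape accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def class_counts(self) -> np.ndarray:
        """Per-class sample counts ``N_j`` (length C)."""
        return np.bincount(self.labels, minlength=self.n_classes)

    def class_rows(self, j: int) -> np.ndarray:
        """Feature rows belonging to class ``j``."""
        return self.features[self.labels == j]

    def subset(self, indices: np.ndarray | list[int]) -> "FeatureDataset":
        """Row subset preserving order; relabels nothing.

        The subset must still contain every class of the parent to satisfy
        the contiguous-label invariant; episode construction guarantees
        this (each class contributes rows to both splits).
        """
        idx = np.asarray(indices, dtype=np.int64)
        return FeatureDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            ids=tuple(self.ids[i] for i in idx),
        )

    @staticmethod
    def from_arrays(
        features: np.ndarray, labels: np.ndarray, ids: tuple[str, ...] = ()
    ) -> "FeatureDataset":
        return FeatureDataset(features=features, labels=labels, ids=ids)

    @staticmethod
    def relabel_first_appearance(raw_labels: np.ndarray) -> tuple[np.ndarray, list]:
        """Map arbitrary label values to ``0..C-1`` by first appearance.

        Returns the integer labels and the ordered list of original label
        values (class ``j`` is ``order[j]``).  Deterministic without
        assuming any semantics of the label values.
        """
        order: list = []
        seen: dict = {}
        out = np.empty(len(raw_labels), dtype=np.int64)
        for i, lab in enumerate(raw_labels):
            key = lab.item() if isinstance(lab, np.generic) else lab
            if key not in seen:
                seen[key] = len(order)
                order.append(key)
            out[i] = seen[key]
        return out, order
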