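"""Synthetic feature tables with the statistical structure the subspace
methods assume, so the whole pipeline is testable without any image data.

Three generators:

* :func:`generate_mixture` — class-conditional Gaussians in M dimensions
  (default M = 512, matching a ResNet-18 penultimate layer), optionally
  rectified at zero to emulate post-ReLU deep-feature statistics.
* :func:`generate_variance_trap` — a binary dataset whose class signal
  lives entirely in one *low-variance* coordinate while the remaining
  coordinates carry large class-independent variance.  Variance-preserving
  reduction (PCA) discards the signal; discriminant analysis keeps it.
  This is the designated surface for demonstrating the DA-over-PCA claim
  without external data.
* :func:`generate_planted_nmf` — Y = K*X* (+ rectified noise) with known
  non-negative factors, for factorization-recovery tests.

All generators are pure functions of their spec: an identical spec (same
seed) reproduces the output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import FeatureDataset, ValidationError

__all__ = [
    "MixtureSpec",
    "PlantedNMFSpec",
    "generate_mixture",
    "generate_variance_trap",
    "generate_planted_nmf",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Class-structured Gaussian mixture specification.

    ``class_means=None`` draws one mean per class from the seed (iid
    N(0, mean_scale²) coordinates); ``within_class_scales=None`` draws
    per-coordinate spreads once from a long-tailed lognormal, mimicking
    the heterogeneous activation scales of deep features.
    """

    n_classes: int = 2
    n_features: int = 512
    per_class_n: tuple[int, ...] = ()
    class_means: Optional[np.ndarray] = None  # (C, M)
    within_class_scales: Optional[np.ndarray] = None  # (M,) > 0
    mean_scale: float = 1.0
    nonneg: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_features < 1:
            raise ValidationError("n_classes and n_features must be ≥ 1")
        per_n = self.per_class_n or tuple([100] * self.n_classes)
        if len(per_n) != self.n_classes or any(n < 1 for n in per_n):
            raise ValidationError(
                f"per_class_n must list ≥1 samples for each of the "
                f"{self.n_classes} classes"
            )
        object.__setattr__(self, "per_class_n", tuple(int(n) for n in per_n))
        if self.class_means is not None:
            cm = np.asarray(self.class_means, dtype=np.float64)
            if cm.shape != (self.n_classes, self.n_features):
                raise ValidationError(
                    f"class_means shape {cm.shape} != "
                    f"({self.n_classes}, {self.n_features})"
                )
            object.__setattr__(self, "class_means", cm)
        if self.within_class_scales is not None:
            sc = np.asarray(self.within_class_scales, dtype=np.float64)
            if sc.shape != (self.n_features,):
                raise ValidationError(
                    f"within_class_scales shape {sc.shape} != ({self.n_features},)"
                )
            if np.any(sc <= 0):
                raise ValidationError("within_class_scales must be positive")
            object.__setattr__(self, "within_class_scales", sc)


def generate_mixture(spec: MixtureSpec) -> FeatureDataset:
    """Draw a class-labelled Gaussian-mixture feature table from a spec."""
    rng = np.random.default_rng(spec.seed)
    means = spec.class_means
    if means is None:
        means = rng.normal(0.0, spec.mean_scale, (spec.n_classes, spec.n_features))
    scales = spec.within_class_scales
    if scales is None:
        # long-tailed per-coordinate spreads, drawn once per spec
        scales = np.exp(rng.normal(-0.5, 0.75, spec.n_features))
    rows = []
    labels = []
    for j, n_j in enumerate(spec.per_class_n):
        rows.append(means[j] + rng.normal(0.0, 1.0, (n_j, spec.n_features)) * scales)
        labels.append(np.full(n_j, j, dtype=np.int64))
    feats = np.vstack(rows)
    if spec.nonneg:
        feats = np.maximum(feats, 0.0)
    return FeatureDataset(features=feats, labels=np.concatenate(labels))


def generate_variance_trap(
    n_per_class: int = 100,
    M: int = 10,
    signal_gap: float = 2.0,
    noise_scales: tuple[float, float] = (5.0, 0.5),
    seed: int = 0,
) -> FeatureDataset:
    """Binary mixture whose class signal hides in the lowest-variance axis.

    Coordinates ``0..M-2`` are class-independent zero-mean Gaussians with
    the large ``noise_scales[0]``; the final coordinate separates the two
    class means by ``signal_gap`` with the small within-class spread
    ``noise_scales[1]``.  The generating model's discriminant direction is
    therefore the last basis vector, while the pooled data's leading
    principal component lies (near-)orthogonal to it — the configuration
    in which variance-preserving reduction fails and discriminant
    reduction succeeds.
    """
    if M < 2:
        raise ValidationError("variance trap needs M ≥ 2 coordinates")
    if n_per_class < 2:
        raise ValidationError("need n_per_class ≥ 2")
    nuisance, signal_noise = (float(s) for s in noise_scales)
    if nuisance <= 0 or signal_noise <= 0:
        raise ValidationError("noise scales must be positive")
    signal_total_var = (signal_gap / 2.0) ** 2 + signal_noise**2
    if signal_total_var >= nuisance**2:
        raise ValidationError(
            "signal coordinate's total variance "
            f"({signal_total_var:.4g}) must stay below the nuisance variance "
            f"({nuisance**2:.4g}); widen noise_scales[0] or shrink signal_gap"
        )
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    feats = np.empty((n, M))
    feats[:, :-1] = rng.normal(0.0, nuisance, (n, M - 1))
    labels = np.repeat(np.array([0, 1], dtype=np.int64), n_per_class)
    centers = np.where(labels == 0, +signal_gap / 2.0, -signal_gap / 2.0)
    feats[:, -1] = centers + rng.normal(0.0, signal_noise, n)
    return FeatureDataset(features=feats, labels=labels)


@dataclass(frozen=True)
class PlantedNMFSpec:
    """Planted non-negative low-rank matrix: Y = K*X* + rectified noise."""

    N: int = 50
    M: int = 40
    true_rank: int = 3
    factor_sparsity: float = 0.0  # fraction of factor entries zeroed
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.true_rank < min(self.N, self.M)):
            raise ValidationError(
                f"true_rank={self.true_rank} must be in 1..min(N,M)-1"
            )
        if not (0.0 <= self.factor_sparsity < 1.0):
            raise ValidationError("factor_sparsity must be in [0, 1)")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be ≥ 0")


def generate_planted_nmf(
    spec: PlantedNMFSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns ``(Y, K_true, X_true)`` with Y ≥ 0 everywhere."""
    rng = np.random.default_rng(spec.seed)
    k = rng.random((spec.N, spec.true_rank))
    x = rng.random((spec.true_rank, spec.M))
    if spec.factor_sparsity > 0:
        k *= rng.random(k.shape) >= spec.factor_sparsity
        x *= rng.random(x.shape) >= spec.factor_sparsity
        # keep the planted rank honest: no all-zero component
        dead_k = ~k.any(axis=0)
        if dead_k.any():
            k[:, dead_k] = rng.random((spec.N, int(dead_k.sum())))
        dead_x = ~x.any(axis=1)
        if dead_x.any():
            x[dead_x, :] = rng.random((int(dead_x.sum()), spec.M))
    y = k @ x
    if spec.noise_scale > 0:
        y = np.maximum(y + rng.normal(0.0, spec.noise_scale, y.shape), 0.0)
    return y, k, x
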