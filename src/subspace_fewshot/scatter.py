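"""Class means and scatter matrices.

For samples y_i grouped into C classes with class means ȳ_j and global
mean ȳ, the per-class (within) scatter is

    S_Wj = Σ_k (y_k^j − ȳ_j)(y_k^j − ȳ_j)ᵀ ,

the pooled within-class scatter is S_W = Σ_j S_Wj, and the between-class
scatter is

    S_B = Σ_j (ȳ_j − ȳ)(ȳ_j − ȳ)ᵀ .

For a binary problem the discriminant machinery uses the variants

    s_b = ȳ_1 − ȳ_2 ,   S̃_B = s_b s_bᵀ ,
    S̃_W = β S_W1 + (1 − β) S_W2 ,   β = (N_2 − 1)/(N_1 + N_2 − 2) ,

i.e. a rank-one between-class scatter and a convex combination of the two
per-class scatters weighted by the *other* class's share of the pooled
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureDataset, ValidationError

__all__ = [
    "ClassMeans",
    "ScatterStats",
    "BinaryScatterStats",
    "compute_class_means",
    "compute_scatter",
    "compute_binary_scatter",
]


@dataclass(frozen=True)
class ClassMeans:
    global_mean: np.ndarray  # ȳ, length M
    class_means: np.ndarray  # (C, M), row j is ȳ_j


@dataclass(frozen=True)
class ScatterStats:
    S_B: np.ndarray  # (M, M) between-class scatter, rank ≤ C−1
    S_W: np.ndarray  # (M, M) pooled within-class scatter
    per_class_S_Wj: np.ndarray  # (C, M, M)


@dataclass(frozen=True)
class BinaryScatterStats:
    s_b: np.ndarray  # ȳ_1 − ȳ_2, length M
    S_tilde_B: np.ndarray  # s_b s_bᵀ, rank ≤ 1
    S_tilde_W: np.ndarray  # β S_W1 + (1−β) S_W2
    beta: float
    n_features: int


def compute_class_means(dataset: FeatureDataset) -> ClassMeans:
    """Global mean ȳ and per-class means ȳ_j of a validated dataset."""
    means = np.stack(
        [dataset.class_rows(j).mean(axis=0) for j in range(dataset.n_classes)]
    )
    return ClassMeans(
        global_mean=dataset.features.mean(axis=0), class_means=means
    )


def compute_scatter(dataset: FeatureDataset) -> ScatterStats:
    """Between-, within- and per-class scatter matrices."""
    means = compute_class_means(dataset)
    M = dataset.n_features
    C = dataset.n_classes
    per_class = np.empty((C, M, M))
    s_b = np.zeros((M, M))
    for j in range(C):
        centered = dataset.class_rows(j) - means.class_means[j]
        per_class[j] = centered.T @ centered
        diff = means.class_means[j] - means.global_mean
        s_b += np.outer(diff, diff)
    # symmetrize away accumulation noise from the Gram products
    per_class = 0.5 * (per_class + np.transpose(per_class, (0, 2, 1)))
    return ScatterStats(
        S_B=0.5 * (s_b + s_b.T), S_W=per_class.sum(axis=0), per_class_S_Wj=per_class
    )


def compute_binary_scatter(dataset: FeatureDataset) -> BinaryScatterStats:
    """Binary-problem scatters s_b, S̃_B, S̃_W and the weight β.

    Only defined for C = 2; class order (hence the sign of s_b and the
    roles of N_1, N_2 in β) is the dataset's label order.
    """
    if dataset.n_classes != 2:
        raise ValidationError(
            "binary scatter statistics are defined only for two-class "
            f"problems (got C={dataset.n_classes}); use compute_scatter for "
            "the multiclass forms"
        )
    stats = compute_scatter(dataset)
    means = compute_class_means(dataset)
    n1, n2 = (int(n) for n in dataset.class_counts)
    if n1 + n2 < 3:
        raise ValidationError("β requires N_1 + N_2 ≥ 3 (pooled dof > 0)")
    beta = (n2 - 1) / (n1 + n2 - 2)
    s_b = means.class_means[0] - means.class_means[1]
    return BinaryScatterStats(
        s_b=s_b,
        S_tilde_B=np.outer(s_b, s_b),
        S_tilde_W=beta * stats.per_class_S_Wj[0] + (1.0 - beta) * stats.per_class_S_Wj[1],
        beta=beta,
        n_features=dataset.n_features,
    )
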