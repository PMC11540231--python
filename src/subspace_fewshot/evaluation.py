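"""Few-shot evaluation protocol: episodes, subspace-then-classifier
accuracy, K-averaged KNN, repeat statistics, and a Z-test between arms.

One *episode* is a seeded per-class train/test split (e.g. 75 train and
25 test rows per class for an 8-class problem → 600/200 rows).  For each
of ``n_repeats`` episodes the configured subspace is fitted on the
training rows only, both splits are projected, KNN accuracy is computed
for each neighbourhood size K (default 1, 5, 10, 15) and averaged over
K; the report carries the per-repeat × per-K table plus the mean and the
(n−1)-denominator standard deviation of the K-averaged accuracies across
repeats.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.spatial.distance
import scipy.stats
from sklearn.svm import SVC

from .data import FeatureDataset, ValidationError
from .nmf import (
    DEFAULT_NMF_ITERS,
    fit_nmf,
    fit_snmf,
    nmf_transform,
)
from .subspaces import (
    DEFAULT_DELTA,
    fit_foley_sammon,
    fit_multiclass_da,
    fit_pca,
    project,
)

__all__ = [
    "EpisodeSplit",
    "EvalConfig",
    "EvalReport",
    "make_episode",
    "knn_accuracy",
    "evaluate_pipeline",
    "z_test_accuracy",
    "SUBSPACE_METHODS",
]

SUBSPACE_METHODS = (
    "feature_space",
    "pca",
    "multiclass_da",
    "foley_sammon",
    "nmf",
    "snmf",
)

DEFAULT_KNN_K = (1, 5, 10, 15)
DEFAULT_N_REPEATS = 10
DEFAULT_NMF_DIM = 30


@dataclass(frozen=True)
class EpisodeSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    per_class_train: int
    per_class_test: int
    seed: int


@dataclass(frozen=True)
class EvalConfig:
    """Protocol constants for one evaluation run.

    Defaults mirror the study protocol: K ∈ {1, 5, 10, 15}, 10 repeats,
    δ = 5e-3, 3000 NMF iterations, subspace dimension 30 for PCA/NMF/SNMF
    and C−1 for multiclass DA (``subspace_dim=None`` selects the
    method-specific default).
    """

    subspace_method: str = "feature_space"
    subspace_dim: Optional[int] = None
    per_class_train: int = 75
    per_class_test: int = 25
    knn_K_values: tuple[int, ...] = DEFAULT_KNN_K
    n_repeats: int = DEFAULT_N_REPEATS
    delta: float = DEFAULT_DELTA
    nmf_iters: int = DEFAULT_NMF_ITERS
    snmf_coupling: float = 1.0
    classifier: str = "knn"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    pca_center: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.subspace_method not in SUBSPACE_METHODS:
            raise ValidationError(
                f"unknown subspace_method {self.subspace_method!r}; "
                f"choose from {SUBSPACE_METHODS}"
            )
        if self.classifier not in ("knn", "svm"):
            raise ValidationError("classifier must be 'knn' or 'svm'")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be ≥ 1")
        if self.per_class_train < 1 or self.per_class_test < 1:
            raise ValidationError("per-class train and test counts must be ≥ 1")
        if not self.knn_K_values or any(k < 1 for k in self.knn_K_values):
            raise ValidationError("knn_K_values must be positive integers")
        if self.subspace_dim is not None and self.subspace_dim < 1:
            raise ValidationError("subspace_dim must be ≥ 1 when given")

    def resolved_dim(self, n_classes: int) -> Optional[int]:
        """Dimension actually used: explicit value, else the method default
        (C−1 for multiclass DA, 1 for Foley–Sammon on binary problems, 30
        for PCA/NMF/SNMF, none for the raw feature space)."""
        if self.subspace_method == "feature_space":
            return None
        if self.subspace_dim is not None:
            return self.subspace_dim
        if self.subspace_method == "multiclass_da":
            return n_classes - 1
        if self.subspace_method == "foley_sammon":
            return 1
        return DEFAULT_NMF_DIM

    def to_dict(self) -> dict:
        return {
            "subspace_method": self.subspace_method,
            "subspace_dim": self.subspace_dim,
            "per_class_train": self.per_class_train,
            "per_class_test": self.per_class_test,
            "knn_K_values": list(self.knn_K_values),
            "n_repeats": self.n_repeats,
            "delta": self.delta,
            "nmf_iters": self.nmf_iters,
            "snmf_coupling": self.snmf_coupling,
            "classifier": self.classifier,
            "svm_C": self.svm_C,
            "svm_gamma": self.svm_gamma,
            "pca_center": self.pca_center,
            "master_seed": self.master_seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "EvalConfig":
        known = {f for f in EvalConfig.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "knn_K_values" in d:
            d["knn_K_values"] = tuple(int(k) for k in d["knn_K_values"])
        return EvalConfig(**d)


@dataclass(frozen=True)
class EvalReport:
    """Per-repeat, per-K accuracies with summary statistics.

    ``mean_accuracy``/``std_accuracy`` follow the K-first convention:
    average over K within each repeat, then mean and (n−1)-std across
    repeats.  ``per_K_mean``/``per_K_std`` keep the per-K breakdown, and
    ``pooled_std`` treats every (repeat, K) cell as an observation, so
    either variance convention can be read out.
    """

    per_repeat_per_K_accuracy: np.ndarray  # (n_repeats, |K|)
    mean_accuracy: float
    std_accuracy: float
    per_K_mean: np.ndarray
    per_K_std: np.ndarray
    pooled_std: float
    config: EvalConfig
    per_repeat_accuracy: np.ndarray = field(default=None)  # K-averaged, (n_repeats,)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "accuracy_table": self.per_repeat_per_K_accuracy.tolist(),
            "per_repeat_accuracy": self.per_repeat_accuracy.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "per_K_mean": self.per_K_mean.tolist(),
            "per_K_std": self.per_K_std.tolist(),
            "pooled_std": self.pooled_std,
        }

    @staticmethod
    def from_dict(d: dict) -> "EvalReport":
        return EvalReport(
            per_repeat_per_K_accuracy=np.asarray(d["accuracy_table"], dtype=float),
            mean_accuracy=float(d["mean_accuracy"]),
            std_accuracy=float(d["std_accuracy"]),
            per_K_mean=np.asarray(d["per_K_mean"], dtype=float),
            per_K_std=np.asarray(d["per_K_std"], dtype=float),
            pooled_std=float(d["pooled_std"]),
            config=EvalConfig.from_dict(d["config"]),
            per_repeat_accuracy=np.asarray(d["per_repeat_accuracy"], dtype=float),
        )


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------

def make_episode(
    dataset: FeatureDataset,
    per_class_train: int,
    per_class_test: int,
    seed: int,
) -> EpisodeSplit:
    """Seeded per-class split without replacement; train/test disjoint."""
    if per_class_train < 1:
        raise ValidationError("per_class_train must be ≥ 1")
    if per_class_test < 1:
        raise ValidationError("per_class_test must be ≥ 1")
    need = per_class_train + per_class_test
    counts = dataset.class_counts
    for j, n_j in enumerate(counts):
        if n_j < need:
            raise ValidationError(
                f"class {j} has {int(n_j)} samples; episode needs "
                f"{per_class_train}+{per_class_test}={need} per class"
            )
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for j in range(dataset.n_classes):
        rows = np.nonzero(dataset.labels == j)[0]
        picked = rng.choice(rows, size=need, replace=False)
        train_idx.append(np.sort(picked[:per_class_train]))
        test_idx.append(np.sort(picked[per_class_train:]))
    return EpisodeSplit(
        train_indices=np.concatenate(train_idx),
        test_indices=np.concatenate(test_idx),
        per_class_train=per_class_train,
        per_class_test=per_class_test,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def knn_accuracy(
    train_proj: np.ndarray,
    train_labels: np.ndarray,
    test_proj: np.ndarray,
    test_labels: np.ndarray,
    K: int,
) -> float:
    """Fraction of test rows classified correctly by K-nearest-neighbour
    majority vote under Euclidean distance.

    Ties (possible for even K or multi-class votes) are broken by the
    nearest neighbour among the tied classes, then by the lowest class
    index — fully deterministic.
    """
    train_proj = np.atleast_2d(np.asarray(train_proj, dtype=np.float64))
    test_proj = np.atleast_2d(np.asarray(test_proj, dtype=np.float64))
    train_labels = np.asarray(train_labels, dtype=np.int64)
    test_labels = np.asarray(test_labels, dtype=np.int64)
    n_train = train_proj.shape[0]
    if K < 1:
        raise ValidationError("K must be ≥ 1")
    if K > n_train:
        raise ValidationError(f"K={K} exceeds the training size {n_train}")
    dist = scipy.spatial.distance.cdist(test_proj, train_proj)
    # stable argsort → deterministic near-tie behaviour (lowest row index wins)
    order = np.argsort(dist, axis=1, kind="stable")[:, :K]
    neigh_labels = train_labels[order]
    n_classes = int(train_labels.max()) + 1
    correct = 0
    for i in range(test_proj.shape[0]):
        votes = np.bincount(neigh_labels[i], minlength=n_classes)
        top = votes.max()
        tied = np.nonzero(votes == top)[0]
        if tied.size == 1:
            pred = int(tied[0])
        else:
            # nearest neighbour among tied classes; order is distance-sorted
            pred = int(tied.min())
            for lab in neigh_labels[i]:
                if lab in tied:
                    pred = int(lab)
                    break
        correct += pred == test_labels[i]
    return correct / test_proj.shape[0]


def _svm_accuracy(
    train_proj: np.ndarray,
    train_labels: np.ndarray,
    test_proj: np.ndarray,
    test_labels: np.ndarray,
    config: EvalConfig,
    seed: int,
) -> float:
    clf = SVC(
        C=config.svm_C, kernel="rbf", gamma=config.svm_gamma, random_state=seed
    )
    clf.fit(train_proj, train_labels)
    return float(np.mean(clf.predict(test_proj) == test_labels))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _fit_and_project(
    train: FeatureDataset,
    test_features: np.ndarray,
    config: EvalConfig,
    repeat_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the configured subspace on the training episode only and project
    both splits into it."""
    method = config.subspace_method
    dim = config.resolved_dim(train.n_classes)
    if method == "feature_space":
        return train.features, np.asarray(test_features, dtype=np.float64)
    if method == "pca":
        sub = fit_pca(train, dim, center=config.pca_center)
        return project(sub, train.features), project(sub, test_features)
    if method == "multiclass_da":
        sub = fit_multiclass_da(train, delta=config.delta, p=dim)
        return project(sub, train.features), project(sub, test_features)
    if method == "foley_sammon":
        basis = fit_foley_sammon(train, L=dim, delta=config.delta)
        return project(basis, train.features), project(basis, test_features)
    if method == "nmf":
        model = fit_nmf(
            train.features, p=dim, n_iter=config.nmf_iters, seed=repeat_seed
        )
        return model.coeff_K, nmf_transform(model, test_features)
    if method == "snmf":
        snmf = fit_snmf(
            train,
            p=dim,
            n_iter=config.nmf_iters,
            seed=repeat_seed,
            coupling_weight=config.snmf_coupling,
        )
        fact = snmf.factorization
        return fact.coeff_K, nmf_transform(fact, test_features)
    raise ValidationError(f"unknown subspace method {method!r}")


def evaluate_pipeline(dataset: FeatureDataset, config: EvalConfig) -> EvalReport:
    """Run the full repeated-episode protocol on a feature dataset.

    Repeat r draws an episode with seed ``master_seed + r``, fits the
    configured subspace on the training rows only, projects both splits,
    and scores the classifier for every K (KNN) or once (SVM, replicated
    across the K axis so the report shape is uniform).
    """
    n_k = len(config.knn_K_values)
    table = np.empty((config.n_repeats, n_k))
    for r in range(config.n_repeats):
        seed = config.master_seed + r
        try:
            split = make_episode(
                dataset, config.per_class_train, config.per_class_test, seed
            )
            train = dataset.subset(split.train_indices)
            test_features = dataset.features[split.test_indices]
            test_labels = dataset.labels[split.test_indices]
            train_proj, test_proj = _fit_and_project(
                train, test_features, config, seed
            )
            if config.classifier == "svm":
                acc = _svm_accuracy(
                    train_proj, train.labels, test_proj, test_labels, config, seed
                )
                table[r, :] = acc
            else:
                for c, k in enumerate(config.knn_K_values):
                    table[r, c] = knn_accuracy(
                        train_proj, train.labels, test_proj, test_labels, k
                    )
        except ValidationError as exc:
            raise ValidationError(f"repeat {r}: {exc}") from exc
    per_repeat = table.mean(axis=1)  # K-averaged first
    std = float(np.std(per_repeat, ddof=1)) if config.n_repeats > 1 else 0.0
    pooled = float(np.std(table.ravel(), ddof=1)) if table.size > 1 else 0.0
    return EvalReport(
        per_repeat_per_K_accuracy=table,
        mean_accuracy=float(per_repeat.mean()),
        std_accuracy=std,
        per_K_mean=table.mean(axis=0),
        per_K_std=(
            np.std(table, axis=0, ddof=1)
            if config.n_repeats > 1
            else np.zeros(n_k)
        ),
        pooled_std=pooled,
        config=config,
        per_repeat_accuracy=per_repeat,
    )


def subspace_fingerprint(
    train: FeatureDataset, config: EvalConfig, repeat_seed: int
) -> str:
    """SHA-256 of the fitted training projection — used to verify that the
    fitted subspace depends on the training episode only."""
    train_proj, _ = _fit_and_project(
        train, train.features[:1], config, repeat_seed
    )
    return hashlib.sha256(np.ascontiguousarray(train_proj).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def z_test_accuracy(
    acc_a: Sequence[float], acc_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided pooled-variance Z-test on per-repeat accuracy means.

    Returns ``(z, p)`` with z = (mean_a − mean_b) / SE using the pooled
    standard deviation of the two arms.  Two constant equal arms give
    z = 0, p = 1; a nonzero mean difference with zero pooled variance
    gives ±inf and the smallest positive p.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValidationError("accuracy vectors must be 1-D and equal length")
    n = a.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 repeats per arm")
    diff = a.mean() - b.mean()
    sp2 = ((n - 1) * a.var(ddof=1) + (n - 1) * b.var(ddof=1)) / (2 * n - 2)
    se = np.sqrt(sp2 * (2.0 / n))
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        z = np.inf if diff > 0 else -np.inf
        return float(z), float(np.finfo(float).tiny)
    z = diff / se
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(max(p, np.finfo(float).tiny))


def _replace_config(config: EvalConfig, **kw) -> EvalConfig:
    """Convenience for sweeps (dimension, method, seed) over a base config."""
    return replace(config, **kw)
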