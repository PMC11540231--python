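"""Non-negative matrix factorization by multiplicative Frobenius updates,
plus a supervised variant for binary problems.

Plain NMF approximates a non-negative data matrix Y (N×M) as Y ≈ K X with
K (N×p) and X (p×M) non-negative, minimizing ‖Y − KX‖_F² by the classic
alternating multiplicative updates

    K ← K ⊙ (Y Xᵀ) / (K X Xᵀ) ,   X ← X ⊙ (Kᵀ Y) / (Kᵀ K X) ,

which keep both factors non-negative and never increase the objective.
Rows of X are the basis vectors; row i of K gives the coordinates of
sample i in the p-dimensional subspace.

The supervised variant (SNMF, binary labels only) couples a label-fit
term into the objective,

    ‖Y − KX‖_F² + λ ‖Z − KQ‖_F² ,

where Z is the N×2 one-hot label matrix and Q (p×2) a non-negative
read-out, so the learned coordinates K are pulled toward being linearly
label-predictive while still reconstructing Y.  All three factors keep
multiplicative updates; at λ = 0 the K and X trajectories coincide with
plain NMF from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import FeatureDataset, ValidationError

__all__ = [
    "NMFFactorization",
    "SNMFModel",
    "fit_nmf",
    "fit_snmf",
    "nmf_transform",
    "reconstruction_error",
    "DEFAULT_NMF_ITERS",
]

#: Iteration count used throughout; large enough that the multiplicative
#: updates have converged on problems of the intended (few-hundred-row) size.
DEFAULT_NMF_ITERS = 3000

#: Pointwise guard added to update denominators; preserves monotonicity to
#: numerical tolerance while ruling out 0/0 on zero rows/columns.
_EPS = 1e-12


@dataclass(frozen=True)
class NMFFactorization:
    basis_X: np.ndarray  # (p, M), non-negative
    coeff_K: np.ndarray  # (N, p), non-negative
    rank_p: int
    objective_trace: np.ndarray  # ‖Y−KX‖_F² after init and each iteration
    n_iter: int
    seed: int
    #: first iteration at which the relative improvement fell below 1e-9
    #: (diagnostic only; the full n_iter is always run)
    converged_at: Optional[int] = None

    @property
    def n_features(self) -> int:
        return self.basis_X.shape[1]


@dataclass(frozen=True)
class SNMFModel:
    factorization: NMFFactorization
    label_weights_Q: np.ndarray  # (p, 2), non-negative read-out
    coupling_weight: float
    class_map: tuple[int, int]  # label order of the one-hot columns
    total_objective_trace: np.ndarray  # reconstruction + λ·label terms


def _validate_nonneg(y: np.ndarray, strict: bool) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValidationError("matrix contains non-finite entries")
    neg = y < 0
    if neg.any():
        if strict:
            raise ValidationError(
                f"{int(neg.sum())} negative entries; NMF requires Y ≥ 0 "
                "(strict mode)"
            )
        y = np.where(neg, 0.0, y)
    return y


def _init_factors(
    rng: np.random.Generator, n: int, m: int, p: int, y_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    # uniform (0, 1] scaled so that (KX) starts on the data's scale
    scale = np.sqrt(max(y_mean, _EPS) / p)
    k = (1.0 - rng.random((n, p))) * scale
    x = (1.0 - rng.random((p, m))) * scale
    return k, x


def fit_nmf(
    train_features: np.ndarray,
    p: int,
    n_iter: int = DEFAULT_NMF_ITERS,
    seed: int = 0,
    *,
    strict: bool = False,
) -> NMFFactorization:
    """Factorize a non-negative matrix as Y ≈ KX by multiplicative updates.

    Negative inputs are clipped to zero by default (post-ReLU deep features
    are non-negative, so this is normally a no-op); ``strict=True`` raises
    instead.  The objective ‖Y−KX‖_F² is recorded after initialization and
    after every iteration; it is non-increasing to numerical tolerance.
    """
    y = _validate_nonneg(train_features, strict)
    n, m = y.shape
    if not (1 <= p < min(n, m)):
        raise ValidationError(f"p={p} out of range 1..min(N,M)-1={min(n, m) - 1}")
    if n_iter < 1:
        raise ValidationError("n_iter must be ≥ 1")
    rng = np.random.default_rng(seed)
    k, x = _init_factors(rng, n, m, p, float(y.mean()))

    trace = np.empty(n_iter + 1)
    trace[0] = np.linalg.norm(y - k @ x) ** 2
    converged_at: Optional[int] = None
    for it in range(1, n_iter + 1):
        k *= (y @ x.T) / (k @ (x @ x.T) + _EPS)
        x *= (k.T @ y) / ((k.T @ k) @ x + _EPS)
        trace[it] = np.linalg.norm(y - k @ x) ** 2
        if (
            converged_at is None
            and trace[it - 1] > 0
            and (trace[it - 1] - trace[it]) / trace[it - 1] < 1e-9
        ):
            converged_at = it
    return NMFFactorization(
        basis_X=x,
        coeff_K=k,
        rank_p=p,
        objective_trace=trace,
        n_iter=n_iter,
        seed=seed,
        converged_at=converged_at,
    )


def nmf_transform(
    model: NMFFactorization,
    new_features: np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    strict: bool = False,
) -> np.ndarray:
    """Coefficients of new rows in a fitted basis (X held fixed).

    Runs the K-update alone until the relative objective change drops
    below ``tol`` or ``max_iter`` iterations — the same multiplicative
    machinery as training, so out-of-sample rows are embedded under the
    training objective.
    """
    y = _validate_nonneg(new_features, strict)
    single = False
    if y.ndim == 1:  # pragma: no cover - _validate_nonneg enforces 2-D
        y = y[None, :]
        single = True
    x = model.basis_X
    if y.shape[1] != x.shape[1]:
        raise ValidationError(
            f"feature width {y.shape[1]} does not match basis M={x.shape[1]}"
        )
    p = model.rank_p
    # deterministic scale-matched start (no randomness needed with X fixed)
    k = np.full((y.shape[0], p), np.sqrt(max(float(y.mean()), _EPS) / p))
    xxt = x @ x.T
    yxt = y @ x.T
    prev = np.linalg.norm(y - k @ x) ** 2
    for _ in range(max_iter):
        k *= yxt / (k @ xxt + _EPS)
        obj = np.linalg.norm(y - k @ x) ** 2
        if prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj
    return k[0] if single else k


def reconstruction_error(model: NMFFactorization, features: np.ndarray) -> float:
    """Frobenius reconstruction error ‖Y − KX‖_F of the fitted factors.

    ``features`` must be the matrix the model was fitted on (shape must
    match the stored K and X).
    """
    y = np.asarray(features, dtype=np.float64)
    k, x = model.coeff_K, model.basis_X
    if y.shape != (k.shape[0], x.shape[1]):
        raise ValidationError(
            f"features shape {y.shape} does not match factorization "
            f"({k.shape[0]}, {x.shape[1]})"
        )
    return float(np.linalg.norm(y - k @ x))


def fit_snmf(
    train: FeatureDataset,
    p: int,
    n_iter: int = DEFAULT_NMF_ITERS,
    seed: int = 0,
    *,
    coupling_weight: float,
    strict: bool = False,
) -> SNMFModel:
    """Supervised NMF for a binary training set.

    Adds λ‖Z − KQ‖_F² to the reconstruction objective (Z the one-hot
    label matrix, λ = ``coupling_weight`` ≥ 0) and updates K, X and Q
    multiplicatively.  K and X are initialized exactly as in plain NMF
    from the same seed, so λ = 0 reproduces the plain trajectories.
    """
    if train.n_classes != 2:
        raise ValidationError(
            "supervised NMF is restricted to binary classification problems "
            f"(got C={train.n_classes})"
        )
    if coupling_weight < 0:
        raise ValidationError(f"coupling_weight must be ≥ 0, got {coupling_weight}")
    y = _validate_nonneg(train.features, strict)
    n, m = y.shape
    if not (1 <= p < min(n, m)):
        raise ValidationError(f"p={p} out of range 1..min(N,M)-1={min(n, m) - 1}")
    lam = float(coupling_weight)
    z = np.zeros((n, 2))
    z[np.arange(n), train.labels] = 1.0

    rng = np.random.default_rng(seed)
    k, x = _init_factors(rng, n, m, p, float(y.mean()))  # same draws as fit_nmf
    q = 1.0 - rng.random((p, 2))

    recon = np.empty(n_iter + 1)
    total = np.empty(n_iter + 1)
    recon[0] = np.linalg.norm(y - k @ x) ** 2
    total[0] = recon[0] + lam * np.linalg.norm(z - k @ q) ** 2
    converged_at: Optional[int] = None
    for it in range(1, n_iter + 1):
        num = y @ x.T + lam * (z @ q.T)
        den = k @ (x @ x.T) + lam * (k @ (q @ q.T)) + _EPS
        k *= num / den
        x *= (k.T @ y) / ((k.T @ k) @ x + _EPS)
        if lam > 0:
            q *= (k.T @ z) / ((k.T @ k) @ q + _EPS)
        recon[it] = np.linalg.norm(y - k @ x) ** 2
        total[it] = recon[it] + lam * np.linalg.norm(z - k @ q) ** 2
        if (
            converged_at is None
            and total[it - 1] > 0
            and (total[it - 1] - total[it]) / total[it - 1] < 1e-9
        ):
            converged_at = it
    fact = NMFFactorization(
        basis_X=x,
        coeff_K=k,
        rank_p=p,
        objective_trace=recon,
        n_iter=n_iter,
        seed=seed,
        converged_at=converged_at,
    )
    return SNMFModel(
        factorization=fact,
        label_weights_Q=q,
        coupling_weight=lam,
        class_map=(0, 1),
        total_objective_trace=total,
    )
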