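"""Linear subspace fits: PCA/SVD, regularized multiclass Fisher DA, and
the recursive orthogonal (Foley–Sammon) discriminant vectors for binary
problems.

Multiclass DA maximizes the Fisher criterion dᵀS_B d / dᵀS_W d, solved as
the generalized eigenproblem S_B d = λ S_W d.  In the few-shot regime
(N < M) S_W is singular, so it is ridge-regularized, Ŝ_W = S_W + δI, with
a small δ (default 5e-3), and the top C−1 eigenvectors of Ŝ_W⁻¹ S_B span
the discriminant subspace.

For a binary problem the Fisher criterion R(d) = dᵀS̃_B d / dᵀS̃_W d has a
single maximizer, d_1 ∝ S̃_W⁻¹ s_b.  The Foley–Sammon construction extends
this to L ≤ M directions: d_n maximizes R subject to d_nᵀd_k = 0 for all
k < n, giving the recursion

    d_n = α_n S̃_W⁻¹ ( s_b − [d_1 … d_{n−1}] S_{n−1}⁻¹ e_1/α_1 ) ,

where S_{n−1} is the Gram matrix with entries d_iᵀ S̃_W⁻¹ d_j and α_n
normalizes to unit length.  Each direction carries a "discrim-value"
γ_n = d_nᵀS̃_B d_n / d_nᵀS̃_W d_n, the analogue of a singular value; the
sequence γ_1 ≥ γ_2 ≥ … ≥ γ_L ≥ 0 orders the basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.linalg

from .data import FeatureDataset, ValidationError
from .scatter import (
    BinaryScatterStats,
    compute_binary_scatter,
    compute_scatter,
)

__all__ = [
    "LinearSubspace",
    "FoleySammonBasis",
    "fit_pca",
    "fit_multiclass_da",
    "fit_foley_sammon",
    "foley_sammon_from_stats",
    "project",
    "discrim_values",
    "fisher_ratio",
    "DEFAULT_DELTA",
]

#: Default ridge added to a (near-)singular within-class scatter.
DEFAULT_DELTA = 5e-3

#: Condition-number threshold beyond which S̃_W is treated as singular and
#: regularized even when the caller passed delta = 0 implicitly via defaults.
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class LinearSubspace:
    """Orthonormal projection basis with its spectrum.

    ``basis`` is ``(M, p)`` with orthonormal columns; ``spectrum`` holds
    singular values (PCA) or generalized eigenvalues (DA) in descending
    order.  ``centering`` is the training mean for PCA and ``None`` for
    discriminant fits (which apply no centering).  For multiclass DA,
    ``eigenvectors`` additionally stores the raw unit-norm generalized
    eigenvectors, which satisfy S_B v = λ(S_W + δI)v but are not mutually
    orthogonal; ``basis`` is their re-orthonormalized span.
    """

    basis: np.ndarray
    spectrum: np.ndarray
    centering: Optional[np.ndarray]
    method_tag: str  # {"pca", "multiclass_da", "foley_sammon"}
    delta_used: float = 0.0
    eigenvectors: Optional[np.ndarray] = None

    @property
    def n_features(self) -> int:
        return self.basis.shape[0]

    @property
    def dim(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class FoleySammonBasis:
    """Orthonormal discriminant directions d_1..d_L with bookkeeping.

    ``gram`` is the L×L matrix of d_iᵀ S̃_W⁻¹ d_j (the S_{n−1} recursion
    state, fully grown); ``alphas`` the normalizing constants; and
    ``discrim_values`` the Fisher ratios γ_n attained by each direction,
    non-increasing.  ``delta_used`` records the ridge actually applied to
    S̃_W (0 when it was well-conditioned and no ridge was requested).
    """

    directions: np.ndarray  # (M, L), orthonormal columns
    alphas: np.ndarray  # (L,)
    gram: np.ndarray  # (L, L)
    discrim_values: np.ndarray  # (L,), non-increasing
    delta_used: float

    @property
    def n_features(self) -> int:
        return self.directions.shape[0]

    @property
    def dim(self) -> int:
        return self.directions.shape[1]


# ---------------------------------------------------------------------------
# sign convention
# ---------------------------------------------------------------------------

def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (ties: lowest
    index), so fitted bases are reproducible across runs and BLAS builds."""
    out = basis.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            out[:, k] = -col
    return out


# ---------------------------------------------------------------------------
# PCA via SVD
# ---------------------------------------------------------------------------

def fit_pca(
    train: FeatureDataset, p: int, *, center: bool = True
) -> LinearSubspace:
    """Principal-component subspace of the training features.

    The training matrix is mean-centered (the mean is stored and reused
    to center any data projected later), decomposed by SVD, and the top-p
    right singular vectors form the basis.  ``center=False`` selects the
    uncentered SVD of the raw feature matrix instead.
    """
    if not (1 <= p <= min(train.n_samples, train.n_features)):
        raise ValidationError(
            f"p={p} out of range 1..min(N={train.n_samples}, M={train.n_features})"
        )
    mean = train.features.mean(axis=0) if center else np.zeros(train.n_features)
    _, s, vt = scipy.linalg.svd(train.features - mean, full_matrices=False)
    return LinearSubspace(
        basis=_fix_signs(vt[:p].T),
        spectrum=s[:p].copy(),
        centering=mean if center else None,
        method_tag="pca",
    )


# ---------------------------------------------------------------------------
# multiclass discriminant analysis
# ---------------------------------------------------------------------------

def fit_multiclass_da(
    train: FeatureDataset,
    delta: float = DEFAULT_DELTA,
    p: Optional[int] = None,
) -> LinearSubspace:
    """Regularized multiclass Fisher discriminant subspace.

    Solves S_B v = λ (S_W + δI) v through the symmetric-definite route
    (Cholesky-factorize Ŝ_W, transform to an ordinary symmetric
    eigenproblem, back-transform) and keeps the eigenvectors of the top
    C−1 (or top-p) eigenvalues.  Raw eigenvectors are unit-normalized and
    kept on the result; the returned projection basis is their
    orthonormalized span.
    """
    if train.n_classes < 2:
        raise ValidationError("multiclass DA needs C ≥ 2 classes")
    if delta <= 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    c_max = train.n_classes - 1
    if p is None:
        p = c_max
    if not (1 <= p <= c_max):
        raise ValidationError(f"p={p} out of range 1..C-1={c_max}")

    stats = compute_scatter(train)
    shat_w = stats.S_W + delta * np.eye(train.n_features)
    # eigh solves the symmetric-definite pencil (S_B, Ŝ_W) via Cholesky
    eigvals, eigvecs = scipy.linalg.eigh(stats.S_B, shat_w)
    order = np.argsort(eigvals)[::-1][:p]
    lam = eigvals[order]
    vecs = eigvecs[:, order]
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    vecs = _fix_signs(vecs)
    # orthonormalize the span, preserving the leading-direction nesting
    q, _ = np.linalg.qr(vecs)
    return LinearSubspace(
        basis=_fix_signs(q),
        spectrum=lam,
        centering=None,
        method_tag="multiclass_da",
        delta_used=delta,
        eigenvectors=vecs,
    )


# ---------------------------------------------------------------------------
# Foley–Sammon recursion (binary)
# ---------------------------------------------------------------------------

def _regularized_within(
    stats: BinaryScatterStats, delta: float, n_train: Optional[int] = None
) -> tuple[np.ndarray, float]:
    """S̃_W plus whatever ridge the conditioning demands.

    A positive ``delta`` is always applied.  With ``delta = 0`` the matrix
    is used as-is unless it is singular or ill-conditioned (condition
    estimate above 1e12, or fewer training rows than features), in which
    case the default ridge is applied — the exact situation a few-shot
    N < M problem creates.
    """
    w = stats.S_tilde_W
    m = w.shape[0]
    if delta > 0:
        return w + delta * np.eye(m), delta
    needs_ridge = False
    if n_train is not None and n_train < m:
        needs_ridge = True
    else:
        try:
            cond = np.linalg.cond(w)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            needs_ridge = True
    if needs_ridge:
        return w + DEFAULT_DELTA * np.eye(m), DEFAULT_DELTA
    return w.copy(), 0.0


def _foley_sammon_from_stats(
    stats: BinaryScatterStats, L: int, delta: float, n_train: Optional[int]
) -> FoleySammonBasis:
    m = stats.n_features
    if not (1 <= L <= m):
        raise ValidationError(f"L={L} out of range 1..M={m}")
    w, delta_used = _regularized_within(stats, delta, n_train)
    try:
        cho = scipy.linalg.cho_factor(w)
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError(
            "within-class scatter is numerically singular even after "
            "regularization; pass delta > 0"
        ) from exc
    w_solve = lambda b: scipy.linalg.cho_solve(cho, b)

    s_b = stats.s_b
    winv_sb = w_solve(s_b)
    nrm = np.linalg.norm(winv_sb)
    if nrm == 0.0:
        # identical class means: every direction is equally (un)informative;
        # the criterion is identically zero and the recursion has no seed
        raise ValidationError(
            "class means coincide (s_b = 0); no discriminant direction exists"
        )
    alpha_1 = 1.0 / nrm
    directions = np.empty((m, L))
    alphas = np.empty(L)
    directions[:, 0] = alpha_1 * winv_sb
    alphas[0] = alpha_1

    # gram grows incrementally: gram[i, j] = d_iᵀ W⁻¹ d_j
    winv_d = np.empty((m, L))  # cached W⁻¹ d_k columns
    winv_d[:, 0] = w_solve(directions[:, 0])
    gram = np.empty((L, L))
    gram[0, 0] = directions[:, 0] @ winv_d[:, 0]

    for n in range(2, L + 1):
        k = n - 1  # number of existing directions
        s_prev = gram[:k, :k]
        rhs = np.zeros(k)
        rhs[0] = 1.0 / alpha_1
        try:
            coef = scipy.linalg.solve(s_prev, rhs, assume_a="sym")
            if not np.all(np.isfinite(coef)):
                raise scipy.linalg.LinAlgError("non-finite solve")
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise ValidationError(
                f"Gram matrix S_{k} is numerically singular: the recursion "
                f"cannot produce direction {n} (rank of the problem is "
                f"exhausted); request L ≤ {k}"
            ) from exc
        resid = s_b - directions[:, :k] @ coef
        d_raw = w_solve(resid)
        # the exact solution is orthogonal to d_1..d_{k}; strip the numerical
        # drift explicitly (two Gram-Schmidt passes) before normalizing
        for _ in range(2):
            d_raw -= directions[:, :k] @ (directions[:, :k].T @ d_raw)
        nrm = np.linalg.norm(d_raw)
        if nrm <= m * np.finfo(float).eps * max(1.0, np.linalg.norm(s_b)):
            raise ValidationError(
                f"direction {n} collapsed to zero (rank exhausted at step {n}); "
                f"request L ≤ {k}"
            )
        alphas[k] = 1.0 / nrm
        directions[:, k] = d_raw / nrm
        winv_d[:, k] = w_solve(directions[:, k])
        gram[k, :k] = directions[:, k] @ winv_d[:, :k]
        gram[:k, k] = directions[:, :k].T @ winv_d[:, k]
        gram[k, k] = directions[:, k] @ winv_d[:, k]

    # deterministic signs; propagate the flips into the Gram bookkeeping
    flipped = _fix_signs(directions)
    signs = np.where((flipped * directions).sum(axis=0) < 0, -1.0, 1.0)
    directions = flipped
    gram = gram * np.outer(signs, signs)
    # γ_n against the same (possibly regularized) W used by the recursion
    proj_b = s_b @ directions
    gammas = (proj_b**2) / np.einsum("ij,jk,ki->i", directions.T, w, directions)
    return FoleySammonBasis(
        directions=directions,
        alphas=alphas,
        gram=gram[:L, :L],
        discrim_values=gammas,
        delta_used=delta_used,
    )


def foley_sammon_from_stats(
    stats: BinaryScatterStats, L: int, delta: float = 0.0
) -> FoleySammonBasis:
    """Run the discriminant-vector recursion directly on binary scatter
    statistics (useful when S̃_W and s_b are given analytically)."""
    if delta < 0:
        raise ValidationError(f"delta must be ≥ 0, got {delta}")
    return _foley_sammon_from_stats(stats, L, delta, n_train=None)


def fit_foley_sammon(
    train: FeatureDataset, L: int, delta: float = 0.0
) -> FoleySammonBasis:
    """Orthogonal discriminant directions for a binary training set.

    ``delta > 0`` forces the ridge S̃_W + δI; ``delta = 0`` applies the
    default ridge only when S̃_W is singular or ill-conditioned (always
    the case when N < M).  Raises if C ≠ 2, L > M, or the recursion runs
    out of rank before producing L directions.
    """
    if train.n_classes != 2:
        raise ValidationError(
            f"Foley–Sammon directions are binary-only (got C={train.n_classes})"
        )
    if delta < 0:
        raise ValidationError(f"delta must be ≥ 0, got {delta}")
    stats = compute_binary_scatter(train)
    return _foley_sammon_from_stats(stats, L, delta, n_train=train.n_samples)


def discrim_values(
    basis: FoleySammonBasis,
    stats: BinaryScatterStats,
    *,
    regularized: bool = True,
) -> np.ndarray:
    """Fisher ratios γ_n = d_nᵀS̃_B d_n / d_nᵀS̃_W d_n of each direction.

    With ``regularized=True`` (default) the denominator uses
    S̃_W + δI with the δ recorded on the basis — the same matrix the
    recursion optimized against; ``regularized=False`` evaluates the raw
    ratio, which errors on an exactly zero denominator.
    """
    if basis.n_features != stats.n_features:
        raise ValidationError(
            f"basis M={basis.n_features} does not match stats M={stats.n_features}"
        )
    d = basis.directions
    w = stats.S_tilde_W
    if regularized and basis.delta_used > 0:
        w = w + basis.delta_used * np.eye(stats.n_features)
    num = (stats.s_b @ d) ** 2
    den = np.einsum("ij,jk,ki->i", d.T, w, d)
    if np.any(den <= 0):
        if basis.delta_used == 0 or not regularized:
            raise ValidationError(
                "zero within-class scatter along a direction and no "
                "regularization recorded; refit with delta > 0"
            )
        raise ValidationError("non-positive denominator in discrim-value")
    return num / den


def fisher_ratio(direction: np.ndarray, stats: BinaryScatterStats) -> float:
    """R(d) = dᵀS̃_B d / dᵀS̃_W d; invariant to rescaling of d."""
    d = np.asarray(direction, dtype=np.float64).ravel()
    if d.shape[0] != stats.n_features:
        raise ValidationError(
            f"direction length {d.shape[0]} does not match M={stats.n_features}"
        )
    nrm = np.linalg.norm(d)
    if nrm == 0.0:
        raise ValidationError("direction must be nonzero")
    d = d / nrm
    den = d @ stats.S_tilde_W @ d
    if den == 0.0:
        raise ValidationError(
            "direction lies in the null space of S̃_W; the ratio is undefined"
        )
    return float((stats.s_b @ d) ** 2 / den)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(
    subspace: Union[LinearSubspace, FoleySammonBasis], features: np.ndarray
) -> np.ndarray:
    """Project feature rows into the subspace's coordinates.

    PCA subtracts the stored training mean first; discriminant bases
    apply no centering.  Accepts a single vector or an ``(n, M)`` matrix.
    """
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if isinstance(subspace, FoleySammonBasis):
        basis = subspace.directions
        centering = None
    else:
        basis = subspace.basis
        centering = subspace.centering
    if x.shape[1] != basis.shape[0]:
        raise ValidationError(
            f"feature width {x.shape[1]} does not match subspace M={basis.shape[0]}"
        )
    if centering is not None:
        x = x - centering
    out = x @ basis
    return out[0] if single else out
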