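# Methods

This note records the statistical models the package implements, the
defaults it ships, what the synthetic generators do and do not emulate,
and the numerical choices made where the mathematics leaves room.

## Setting

N labelled samples y_i ∈ R^M (rows of a feature table; in the intended
use, penultimate-layer activations of a frozen network, M = 512) in C
classes Λ_j of sizes N_j. The regime of interest is N ≲ M: too little
data to fit in the ambient space, so classification happens after a
linear reduction fitted on a small training episode.

## Scatter statistics

Class means ȳ_j and global mean ȳ; per-class scatter
S_Wj = Σ_k (y_k^j − ȳ_j)(y_k^j − ȳ_j)ᵀ; pooled within-class scatter
S_W = Σ_j S_Wj; between-class scatter S_B = Σ_j (ȳ_j − ȳ)(ȳ_j − ȳ)ᵀ
(unweighted per-class sum — note that the classical total-scatter
decomposition then reads Σ_i (y_i − ȳ)(y_i − ȳ)ᵀ = S_W + Σ_j N_j (ȳ_j −
ȳ)(ȳ_j − ȳ)ᵀ, i.e. the identity holds with the class-size-weighted
between term, which the tests assert). For binary problems the
discriminant machinery uses s_b = ȳ_1 − ȳ_2, S̃_B = s_b s_bᵀ and the
convex combination S̃_W = β S_W1 + (1−β) S_W2 with
β = (N_2 − 1)/(N_1 + N_2 − 2): each class's scatter is weighted by the
other class's share of the pooled degrees of freedom, so the smaller
class is not drowned out. Class indices follow first appearance in the
label column — deterministic without assuming label semantics — and β's
(N_1, N_2) follow that order. Inputs are validated for finiteness up
front (scatter products silently absorb NaN otherwise), and M is capped
at 4096 so the dense M×M allocations stay an explicit choice.

## Subspaces

**PCA/SVD.** Top-p right singular vectors of the training matrix after
subtracting the training mean; the stored mean also centers any data
projected later (test rows are never used in the fit). Centering is the
default because the comparison target is PCA; the uncentered SVD of the
raw matrix is selectable (`center=False`) since either convention is
defensible for non-negative deep features.

**Multiclass DA.** Fisher's criterion max_d dᵀS_B d / dᵀS_W d leads to
S_B d = λ S_W d. In the few-shot regime S_W is singular, so the pencil
is regularized: Ŝ_W = S_W + δI with δ = 5·10⁻³ by default. The
eigenproblem is solved in its symmetric-definite form (Cholesky-
factorize Ŝ_W, transform, symmetric eigensolve, back-transform — via
`scipy.linalg.eigh(S_B, Ŝ_W)`) rather than forming Ŝ_W⁻¹S_B, which is
mathematically identical and numerically stabler. The top C−1 (or a
requested p ≤ C−1) eigenvectors are kept. Generalized eigenvectors are
not mutually orthogonal, so the result carries both: the raw unit-norm
eigenvectors (for residual checks and spectra) and a QR-orthonormalized
basis of their span, which is what projection uses. Requesting more
directions than C−1 errors rather than silently truncating.

**Foley–Sammon directions (binary).** d_1 = α_1 S̃_W⁻¹ s_b with α_1
normalizing to unit length; thereafter
d_n = α_n S̃_W⁻¹ (s_b − [d_1 … d_{n−1}] S_{n−1}⁻¹ e_1/α_1), where
S_{n−1} is the Gram matrix d_iᵀS̃_W⁻¹d_j, grown incrementally and solved
by factorization; failure (rank exhaustion) is reported at the first
unrecoverable step n. S̃_W⁻¹ applications reuse one cached Cholesky
factorization. Exact arithmetic makes each new direction orthogonal to
all predecessors; in floating point the orthogonality drifts (observed
~10⁻⁵ by L = 10 on M = 10 problems), so each new direction is explicitly
re-orthogonalized against its predecessors (two Gram–Schmidt passes)
before normalization — a stabilization of the constraint, not a change
of the optimum. Discrim-values γ_n = d_nᵀS̃_B d_n / d_nᵀS̃_W d_n are
evaluated by default against the same (regularized, see below) S̃_W the
recursion optimized, with the raw-denominator variant selectable; the
sequence is non-increasing.

**Regularization of S̃_W.** The binary within-class scatter is singular
in exactly the situations the few-shot regime creates (N < M). A caller-
supplied δ > 0 is always applied as S̃_W + δI; with δ = 0 the matrix is
used as-is unless N < M or its condition estimate exceeds 10¹², in which
case the default δ = 5·10⁻³ is applied and recorded on the result.

**Sign convention.** Every fitted basis column has its largest-magnitude
entry made positive (ties broken by lowest index), so repeated fits are
bit-identical across runs and BLAS builds.

## NMF and supervised NMF

Y ≈ KX with K (N×p), X (p×M) ≥ 0, fitted by the alternating
multiplicative updates K ← K⊙(YXᵀ)/(KXXᵀ), X ← X⊙(KᵀY)/(KᵀKX), which
never increase ‖Y − KX‖²_F. Denominators carry a pointwise guard
ε = 10⁻¹² (zero rows/columns otherwise produce 0/0); the guard preserves
monotonicity to ~10⁻⁹ relative per step, which is the tolerance the
tests use. Initialization draws K, X uniformly from (0, 1] scaled by
√(mean(Y)/p) so the first product KX starts on the data's scale; all
randomness flows through one seeded generator. The full iteration budget
(default 3000 — comfortably past convergence at the few-hundred-row
problem sizes this package targets) is always run; the iteration at
which relative improvement first drops below 10⁻⁹ is recorded as a
diagnostic. Negative inputs are clipped at zero by default (post-ReLU
deep features are non-negative, so this is normally a no-op; the clip
count is available by comparing inputs) with a strict mode that errors
instead.

Out-of-sample rows are embedded by running the K-update alone with X
fixed, from a deterministic scale-matched start, until the relative
objective change is below 10⁻⁸ or 500 iterations — the same objective
and code path as training, cross-checked in tests against a per-row
non-negative least-squares oracle.

**Supervised variant (binary only).** The objective becomes
‖Y − KX‖²_F + λ‖Z − KQ‖²_F with Z the N×2 one-hot label matrix and Q a
p×2 non-negative read-out; K's update numerator/denominator gain the
λZQᵀ / λKQQᵀ terms and Q gets its own multiplicative update. All factors
stay non-negative and the combined objective is non-increasing. K and X
are initialized with exactly the same seeded draws as plain NMF (Q is
drawn afterwards), so λ = 0 reproduces the plain trajectories
bit-for-bit. The coupling weight has no canonical value; `fit_snmf`
requires it explicitly, and the evaluation config defaults to λ = 1 —
equal weight on reconstruction and label fit — as this package's own
choice, to be tuned per application. Multiclass label coupling is out of
scope.

## Evaluation protocol

An episode draws, per class, `per_class_train` + `per_class_test` rows
without replacement (seeded); e.g. an 8-class problem at 75/25 yields
600 training and 200 test rows. For repeat r (r = 0..9 by default) the
episode seed is `master_seed + r`; the configured subspace is fitted on
the training episode only; both splits are projected; KNN accuracy is
computed for each K ∈ {1, 5, 10, 15} and averaged over K; the report
carries the full repeat × K table, the mean and (n−1)-std of the
K-averaged accuracies across repeats, the per-K breakdown, and a pooled
std over all cells — so either variance convention (across repeats, or
pooling K-level variation) can be read out.

KNN uses Euclidean distance in double precision with a stable sort, and
a deterministic tie-break: majority vote; ties go to the tied class with
the nearest neighbour, then to the lowest class index. The SVM arm is a
standard RBF-kernel SVC with seeded state; its hyperparameters (C,
gamma) come from the config. NMF-based arms seed each repeat's
factorization with the episode seed, so the whole report is a pure
function of the config.

Between-arm significance uses a two-sample pooled-variance Z-test on the
per-repeat (K-averaged) accuracies: z = (ā − b̄)/√(s_p²·2/n), two-sided
normal p-value. Two constant equal arms give z = 0, p = 1; a nonzero
difference with zero pooled variance gives ±∞ and the smallest positive
p rather than an error.

## Synthetic generators

All generators are pure functions of their spec (seed included).

* **Gaussian mixtures** emulate class-structured deep features: one mean
  per class (given, or drawn from the seed), per-coordinate within-class
  scales drawn once per spec from a lognormal — a long-tailed choice
  mimicking the heterogeneous per-unit activation scales of trained
  networks — and optional rectification at zero for post-ReLU
  non-negativity. This is an emulation target, not a claim about any
  particular network: real deep features have correlated coordinates and
  non-Gaussian tails that these mixtures do not reproduce, so passing
  tests demonstrate correctness of the machinery on data satisfying the
  methods' assumptions, not performance on any real dataset.
* **Variance trap**: binary, M coordinates; coordinates 0..M−2 are
  class-independent with a large scale (default 5.0), the last
  coordinate separates the class means by `signal_gap` (default 2.0)
  with a small spread (default 0.5). The generating discriminant
  direction is the last basis vector, while its total variance
  (gap²/4 + 0.25 = 1.25) is far below the nuisance variance (25), so the
  leading principal component is near-orthogonal to the signal — the
  precondition is checked and reported. At these defaults the 1-D
  discriminant subspace classifies at ≈ 2σ-gap Bayes level (~98%) and
  the 1-D principal subspace at chance.
* **Planted NMF**: Y = K*X* with uniform (0,1) factors, optional factor
  sparsity (with a guard that no component dies), optional rectified
  Gaussian noise; ground-truth factors are returned for recovery tests.

## Problem sizes used in verification

The automated checks run at desk scale, chosen to exercise the regime
the methods target while keeping the full suite fast: 50 random binary
problems (N = 60, M = 5..20) for the discriminant-vector oracle suite;
multiclass problems up to 8 classes in 16 dimensions; NMF on 50×40
matrices for 20 × 3000 iterations; and the variance-trap comparison on
10 generated datasets × 10 episodes each at 75/25 rows per class.

## Known limitations

* Scatter computation is dense and in-memory (M ≤ 4096); no streaming.
* Supervised NMF is binary-only; no kernel/sparse discriminant variants;
  no automatic NMF rank selection.
* The image→feature extractor is a plugin contract only: the package
  ships no network weights and no deep-learning dependency. Image
  standardization is per-image by default (per-channel selectable).
* The Z-test treats per-repeat accuracies as independent; repeated
  episodes drawn from one finite table overlap, so its p-values are
  optimistic for small tables (a caveat inherent to the protocol, noted
  in the report header).
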