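# subspace-fewshot

Few-shot image classification with classical subspace methods on deep
features.

## The problem

Medical image collections are often tiny — a few hundred labelled images
per task. A practical recipe in this regime is to freeze a pre-trained
network (e.g. ResNet-18), take its penultimate-layer activations as a
fixed embedding (M = 512 features per image), and run classical pattern
recognition in that space. With N training images comparable to or
smaller than M, dimensionality reduction is mandatory — but the default
choice, PCA/SVD, preserves *variance*, and the variance of a labelled
mixture need not lie where the class separation does. This package
implements, on top of any labelled feature table, the two supervised /
structured alternatives and the evaluation protocol needed to compare
them:

* **PCA / SVD subspace** — top-p right singular vectors of the (mean-
  centered) training matrix.
* **Multiclass discriminant analysis (DA)** — maximize the Fisher
  criterion dᵀS_B d / dᵀS_W d by solving the generalized eigenproblem
  S_B d = λ(S_W + δI)d, with a small ridge δ (default 5·10⁻³) because
  S_W is singular when N < M; up to C−1 directions for C classes.
* **Foley–Sammon discriminant vectors** (binary problems) — a sequence
  d₁, d₂, … of mutually *orthogonal* unit directions, each maximizing
  the binary Fisher ratio R(d) = dᵀS̃_B d / dᵀS̃_W d subject to
  orthogonality with its predecessors:

      d₁ ∝ S̃_W⁻¹ s_b,
      dₙ ∝ S̃_W⁻¹ ( s_b − [d₁ … dₙ₋₁] Sₙ₋₁⁻¹ e₁/α₁ ),   (Sₙ₋₁)ᵢⱼ = dᵢᵀS̃_W⁻¹dⱼ,

  where s_b = ȳ₁ − ȳ₂, S̃_B = s_b s_bᵀ and S̃_W = βS_W1 + (1−β)S_W2 with
  β = (N₂−1)/(N₁+N₂−2). Each direction carries a "discrim-value"
  γₙ = dₙᵀS̃_B dₙ / dₙᵀS̃_W dₙ, the discriminant analogue of a singular
  value, with γ₁ ≥ γ₂ ≥ … ≥ 0.
* **NMF / supervised NMF** — factorize non-negative features Y ≈ KX by
  multiplicative Frobenius updates (K as coordinates, rows of X as
  parts); the supervised variant adds a label-coupling term
  λ‖Z − KQ‖²_F for binary problems.

Evaluation follows a repeated-episode few-shot protocol: per-class
train/test splits (e.g. 75/25 per class), subspaces fitted on the
training episode only, KNN accuracy averaged over K ∈ {1,5,10,15},
mean ± std over 10 seeded repeats, and a pooled Z-test between method
arms. A synthetic-data module generates class-structured Gaussian
mixtures, planted low-rank non-negative matrices, and an adversarial
"variance-trap" mixture whose class signal hides in the lowest-variance
coordinate — the cleanest way to see DA succeed exactly where PCA fails.

## Worked example

Generate a variance-trap table, evaluate 1-D discriminant vs 1-D
principal subspaces, and test the difference:

```bash
subspace-fewshot simulate --kind variance-trap --seed 1 --out trap.csv
subspace-fewshot evaluate --features trap.csv --method fs  --dim 1 --seed 0 --out da.json
subspace-fewshot evaluate --features trap.csv --method svd --dim 1 --seed 0 --out pca.json
subspace-fewshot compare --report-a da.json --report-b pca.json
```

prints

```
foley_sammon accuracy: 0.9865 ± 0.0125 (10 repeats, K=[1, 5, 10, 15])
pca accuracy: 0.4715 ± 0.0639 (10 repeats, K=[1, 5, 10, 15])
{
  "mean_a": 0.9865,
  "mean_b": 0.4715000000000001,
  "z_statistic": 25.02865435666997,
  "p_value": 2.9819297782501414e-138
}
```

The discriminant direction recovers the class signal (98.7% accuracy);
the leading principal component points at pure nuisance variance and
classifies at chance (47%). The Z-test confirms the gap is far beyond
sampling noise.

The same workflow runs from Python:

```python
import subspace_fewshot as sf

ds = sf.generate_variance_trap(seed=1)
cfg = sf.EvalConfig(subspace_method="foley_sammon", subspace_dim=1, master_seed=0)
report = sf.evaluate_pipeline(ds, cfg)
print(report.mean_accuracy, report.std_accuracy)
```

Sweep studies (accuracy vs dimension, NMF rank vs reconstruction error,
accuracy vs dataset size) live in `scripts/synthetic_study.py`.

## Layout

```
src/subspace_fewshot/
  data.py        feature-table container and validation
  scatter.py     class means, S_B / S_W / per-class and binary scatters
  subspaces.py   PCA, regularized multiclass DA, Foley–Sammon recursion
  nmf.py         NMF + supervised NMF by multiplicative updates
  evaluation.py  episodes, KNN/SVM, repeat statistics, Z-test
  synthetic.py   mixture / variance-trap / planted-NMF generators
  io.py          CSV + HDF5 tables, model serialization, reports, config
  extractors.py  image→feature plugin contract (no DL framework required)
  cli.py         simulate / evaluate / compare / extract
```

See `docs/methods.md` for the model details, parameter defaults and
numerical choices.
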