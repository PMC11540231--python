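#!/usr/bin/env python
"""Synthetic sweep studies mirroring the evaluation protocol's standard
experiment shapes on generated data:

* ``da-vs-pca-dims`` — classification accuracy of discriminant vs
  principal subspaces as the subspace dimension grows (variance-trap
  data, where the two methods must diverge at low dimension).
* ``nmf-dims`` — NMF reconstruction error and KNN accuracy as the
  factorization rank grows, over several random initializations.
* ``dataset-size`` — accuracy of the DA and PCA subspaces as the
  per-class training budget grows.

Each study prints a table and writes it as CSV.

Usage::

    python scripts/synthetic_study.py --study da-vs-pca-dims --seed 0 --out sweep.csv
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import subspace_fewshot as sf


def study_da_vs_pca_dims(seed: int) -> pd.DataFrame:
    ds = sf.generate_variance_trap(n_per_class=100, M=10, seed=seed)
    rows = []
    for dim in range(1, 6):
        for method in ("foley_sammon", "pca"):
            cfg = sf.EvalConfig(
                subspace_method=method,
                subspace_dim=dim,
                per_class_train=75,
                per_class_test=25,
                n_repeats=10,
                master_seed=seed,
            )
            rep = sf.evaluate_pipeline(ds, cfg)
            rows.append(
                {
                    "dimension": dim,
                    "method": method,
                    "mean_accuracy": rep.mean_accuracy,
                    "std_accuracy": rep.std_accuracy,
                }
            )
    return pd.DataFrame(rows)


def study_nmf_dims(seed: int) -> pd.DataFrame:
    spec = sf.MixtureSpec(
        n_classes=4,
        n_features=64,
        per_class_n=(60,) * 4,
        mean_scale=1.5,
        nonneg=True,
        seed=seed,
    )
    ds = sf.generate_mixture(spec)
    rows = []
    for p in (5, 10, 20, 30):
        errors, accs = [], []
        for init in range(5):
            model = sf.fit_nmf(ds.features, p=p, n_iter=800, seed=seed + init)
            errors.append(
                sf.reconstruction_error(model, ds.features)
                / np.linalg.norm(ds.features)
            )
            cfg = sf.EvalConfig(
                subspace_method="nmf",
                subspace_dim=p,
                per_class_train=40,
                per_class_test=15,
                n_repeats=3,
                nmf_iters=800,
                master_seed=seed + init,
            )
            accs.append(sf.evaluate_pipeline(ds, cfg).mean_accuracy)
        rows.append(
            {
                "rank_p": p,
                "mean_rel_reconstruction_error": float(np.mean(errors)),
                "std_rel_reconstruction_error": float(np.std(errors, ddof=1)),
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def study_dataset_size(seed: int) -> pd.DataFrame:
    spec = sf.MixtureSpec(
        n_classes=4,
        n_features=32,
        per_class_n=(160,) * 4,
        mean_scale=1.0,
        seed=seed,
    )
    ds = sf.generate_mixture(spec)
    rows = []
    for train_per_class in (10, 25, 50, 100):
        for method in ("multiclass_da", "pca"):
            cfg = sf.EvalConfig(
                subspace_method=method,
                subspace_dim=3,
                per_class_train=train_per_class,
                per_class_test=25,
                n_repeats=5,
                master_seed=seed,
            )
            rep = sf.evaluate_pipeline(ds, cfg)
            rows.append(
                {
                    "train_per_class": train_per_class,
                    "method": method,
                    "mean_accuracy": rep.mean_accuracy,
                    "std_accuracy": rep.std_accuracy,
                }
            )
    return pd.DataFrame(rows)


STUDIES = {
    "da-vs-pca-dims": study_da_vs_pca_dims,
    "nmf-dims": study_nmf_dims,
    "dataset-size": study_dataset_size,
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", choices=sorted(STUDIES), required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()
    table = STUDIES[args.study](args.seed)
    print(table.to_string(index=False))
    if args.out is not None:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(args.out, index=False)


if __name__ == "__main__":
    main()
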