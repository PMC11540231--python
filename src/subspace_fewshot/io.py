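"""Readers and writers: feature tables (CSV / HDF5), fitted-subspace and
factorization containers (HDF5), evaluation reports (JSON + CSV), and the
YAML run configuration.

CSV feature tables use the header ``id,label,f0..f{M-1}`` (comma-separated,
UTF-8, ``.`` decimal).  The HDF5 layout holds datasets ``/features``
(N×M float64), ``/labels`` (N) and ``/ids`` (N), all 0-based row-major.
Arbitrary label values are mapped to class indices 0..C−1 by order of
first appearance in the file.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import FeatureDataset, ValidationError
from .evaluation import EvalConfig, EvalReport
from .nmf import NMFFactorization
from .subspaces import FoleySammonBasis, LinearSubspace

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "save_subspace",
    "load_subspace",
    "save_factorization",
    "load_factorization",
    "write_report",
    "read_report",
    "RunConfig",
    "load_run_config",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise ValidationError(f"unknown format {fmt!r}; use 'csv' or 'hdf5'")
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    return "csv"


def read_feature_table(
    path: PathLike, format: Optional[str] = None
) -> FeatureDataset:
    """Load and validate a feature table; row order is preserved.

    Raw label values (strings or numbers) become class indices 0..C−1 by
    first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("features", "labels"):
                if key not in f:
                    raise ValidationError(f"{path}: missing dataset /{key}")
            feats = np.asarray(f["features"], dtype=np.float64)
            raw_labels = np.asarray(f["labels"])
            ids = (
                tuple(
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in np.asarray(f["ids"])
                )
                if "ids" in f
                else ()
            )
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[0] == 0:
            raise ValidationError(f"{path}: table has zero rows")
        for col in ("id", "label"):
            if col not in df.columns:
                raise ValidationError(f"{path}: missing required column {col!r}")
        feat_cols = [c for c in df.columns if c not in ("id", "label")]
        if not feat_cols:
            raise ValidationError(f"{path}: no feature columns (expected f0..)")
        feats_df = df[feat_cols].apply(pd.to_numeric, errors="coerce")
        if feats_df.isna().any().any():
            bad = feats_df.columns[feats_df.isna().any()][0]
            raise ValidationError(f"{path}: non-numeric entries in column {bad!r}")
        feats = feats_df.to_numpy(dtype=np.float64)
        raw_labels = df["label"].to_numpy()
        ids = tuple(str(v) for v in df["id"])
    labels, _ = FeatureDataset.relabel_first_appearance(raw_labels)
    return FeatureDataset(features=feats, labels=labels, ids=ids)


def write_feature_table(
    dataset: FeatureDataset, path: PathLike, format: Optional[str] = None
) -> None:
    """Write a feature table in the shared CSV or HDF5 layout."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=dataset.features)
            f.create_dataset("labels", data=dataset.labels)
            f.create_dataset(
                "ids", data=np.array([s.encode() for s in dataset.ids])
            )
    else:
        cols = {"id": list(dataset.ids), "label": dataset.labels}
        for j in range(dataset.n_features):
            cols[f"f{j}"] = dataset.features[:, j]
        # %.17g round-trips float64 exactly
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# fitted models (HDF5)
# ---------------------------------------------------------------------------

def save_subspace(
    subspace: Union[LinearSubspace, FoleySammonBasis], path: PathLike
) -> None:
    """Serialize a fitted basis; round-trips bit-identically (float64)."""
    with h5py.File(Path(path), "w") as f:
        if isinstance(subspace, FoleySammonBasis):
            f.create_dataset("basis", data=subspace.directions)
            f.create_dataset("spectrum", data=subspace.discrim_values)
            f.create_dataset("alphas", data=subspace.alphas)
            f.create_dataset("gram", data=subspace.gram)
            f.attrs["method_tag"] = "foley_sammon"
            f.attrs["delta"] = subspace.delta_used
        else:
            f.create_dataset("basis", data=subspace.basis)
            f.create_dataset("spectrum", data=subspace.spectrum)
            if subspace.centering is not None:
                f.create_dataset("centering", data=subspace.centering)
            if subspace.eigenvectors is not None:
                f.create_dataset("eigenvectors", data=subspace.eigenvectors)
            f.attrs["method_tag"] = subspace.method_tag
            f.attrs["delta"] = subspace.delta_used


def load_subspace(path: PathLike) -> Union[LinearSubspace, FoleySammonBasis]:
    with h5py.File(Path(path), "r") as f:
        tag = f.attrs["method_tag"]
        delta = float(f.attrs["delta"])
        if tag == "foley_sammon":
            return FoleySammonBasis(
                directions=np.asarray(f["basis"]),
                alphas=np.asarray(f["alphas"]),
                gram=np.asarray(f["gram"]),
                discrim_values=np.asarray(f["spectrum"]),
                delta_used=delta,
            )
        return LinearSubspace(
            basis=np.asarray(f["basis"]),
            spectrum=np.asarray(f["spectrum"]),
            centering=np.asarray(f["centering"]) if "centering" in f else None,
            method_tag=str(tag),
            delta_used=delta,
            eigenvectors=(
                np.asarray(f["eigenvectors"]) if "eigenvectors" in f else None
            ),
        )


def save_factorization(model: NMFFactorization, path: PathLike) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("X", data=model.basis_X)
        f.create_dataset("K", data=model.coeff_K)
        f.create_dataset("objective_trace", data=model.objective_trace)
        f.attrs["p"] = model.rank_p
        f.attrs["seed"] = model.seed
        f.attrs["n_iter"] = model.n_iter
        if model.converged_at is not None:
            f.attrs["converged_at"] = model.converged_at


def load_factorization(path: PathLike) -> NMFFactorization:
    with h5py.File(Path(path), "r") as f:
        return NMFFactorization(
            basis_X=np.asarray(f["X"]),
            coeff_K=np.asarray(f["K"]),
            rank_p=int(f.attrs["p"]),
            objective_trace=np.asarray(f["objective_trace"]),
            n_iter=int(f.attrs["n_iter"]),
            seed=int(f.attrs["seed"]),
            converged_at=(
                int(f.attrs["converged_at"]) if "converged_at" in f.attrs else None
            ),
        )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(
    report: EvalReport, path: PathLike, provenance: Optional[dict] = None
) -> None:
    """Emit a report as JSON (full) plus a companion CSV accuracy table.

    The JSON parses back to an equal report via :func:`read_report`.  The
    companion CSV (same stem, ``.csv`` suffix) holds the per-repeat,
    per-K accuracy table.
    """
    path = Path(path)
    payload = report.to_dict()
    payload["significance_test"] = (
        "two-sample pooled-variance Z-test on per-repeat K-averaged accuracies"
    )
    if provenance:
        payload["provenance"] = provenance
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    cols = {"repeat": np.arange(report.per_repeat_per_K_accuracy.shape[0])}
    for c, k in enumerate(report.config.knn_K_values):
        cols[f"K={k}"] = report.per_repeat_per_K_accuracy[:, c]
    cols["K_averaged"] = report.per_repeat_accuracy
    pd.DataFrame(cols).to_csv(path.with_suffix(".csv"), index=False)


def read_report(path: PathLike) -> EvalReport:
    payload = json.loads(Path(path).read_text())
    return EvalReport.from_dict(payload)


# ---------------------------------------------------------------------------
# run configuration (YAML)
# ---------------------------------------------------------------------------

_RUN_CONFIG_KEYS = {
    "features",
    "out",
    "log_level",
    "eval",
}


class RunConfig:
    """Structured YAML run configuration.

    Top-level keys: ``features`` (input table path), ``out`` (report
    path), ``log_level``, and ``eval`` (an :class:`EvalConfig` mapping).
    Unknown keys at either level are rejected.
    """

    def __init__(
        self,
        features: Optional[str] = None,
        out: Optional[str] = None,
        log_level: str = "INFO",
        eval: Optional[dict] = None,
    ):
        self.features = features
        self.out = out
        self.log_level = log_level
        self.eval_config = EvalConfig.from_dict(eval or {})

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "out": self.out,
            "log_level": self.log_level,
            "eval": self.eval_config.to_dict(),
        }


def load_run_config(path: PathLike) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _RUN_CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
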