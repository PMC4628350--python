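"""Delimited-text I/O for biomarker tables.

The interchange format is CSV with a header row: one column of labels
(accepted encodings: {1, -1}, {1, 0}, {case, control}, or an explicit
mapping), the remaining numeric columns as markers, optionally some
designated as covariates.  Rows with missing values are dropped with a
counted warning.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .comparators import LinearComboModel
from .covariate import CovariateKMEModel
from .data import BiomarkerSample
from .kernels import KernelSpec
from .kme import KMEModel

_DEFAULT_MAPS = (
    {1: 1.0, -1: -1.0},
    {1: 1.0, 0: -1.0},
    {"case": 1.0, "control": -1.0},
)


def _map_labels(raw: pd.Series, label_map: dict | None) -> np.ndarray:
    vals = raw.tolist()
    candidates = [label_map] if label_map is not None else list(_DEFAULT_MAPS)
    for mapping in candidates:
        if all(v in mapping for v in vals):
            return np.asarray([mapping[v] for v in vals], dtype=float)
    raise ValueError(f"cannot map label values {sorted(set(map(str, vals)))} to +1/-1")


def read_biomarker_csv(path, label_column: str = "label",
                       covariate_columns: list[str] | None = None,
                       label_map: dict | None = None) -> BiomarkerSample:
    """Read a labelled biomarker table from CSV."""
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    n_raw = len(df)
    df = df.dropna()
    dropped = n_raw - len(df)
    if dropped:
        warnings.warn(f"dropped {dropped} row(s) with missing values", stacklevel=2)
    if len(df) < 2:
        raise ValueError("fewer than 2 complete rows")
    y = _map_labels(df[label_column], label_map)
    cov_cols = list(covariate_columns or [])
    marker_cols = [c for c in df.columns if c != label_column and c not in cov_cols]
    try:
        X = df[marker_cols].to_numpy(dtype=float)
        Z = df[cov_cols].to_numpy(dtype=float) if cov_cols else None
    except ValueError as exc:
        raise ValueError(f"non-numeric marker/covariate values: {exc}") from exc
    sample = BiomarkerSample(X, y, Z)
    sample.require_both_classes()
    return sample


def write_biomarker_csv(path, sample: BiomarkerSample,
                        marker_names: list[str] | None = None,
                        covariate_names: list[str] | None = None) -> None:
    """Write a sample as CSV (columns marker_1..m, label, covariates)."""
    names = marker_names or [f"marker_{j + 1}" for j in range(sample.m)]
    df = pd.DataFrame(sample.X, columns=names)
    df["label"] = sample.y.astype(int)
    if sample.Z is not None:
        znames = covariate_names or [f"covariate_{j + 1}" for j in range(sample.Z.shape[1])]
        for j, name in enumerate(znames):
            df[name] = sample.Z[:, j]
    df.to_csv(path, index=False)


def save_model(path, model) -> None:
    """Serialize any fitted model (kernel machine, covariate-adjusted, or
    linear comparator) to a single JSON document."""
    if isinstance(model, KMEModel):
        doc = {"type": "kme", "payload": json.loads(model.to_json())}
    elif isinstance(model, CovariateKMEModel):
        doc = {"type": "cov_kme", "payload": {
            "a": model.a.tolist(), "b": model.b.tolist(),
            "X_train": model.X_train.tolist(), "Z_train": model.Z_train.tolist(),
            "kernel_g": vars(model.kernel_g) | {}, "kernel_c": vars(model.kernel_c) | {},
            "lam": model.lam, "delta": model.delta, "pi_model": model.pi_model}}
    elif isinstance(model, LinearComboModel):
        doc = {"type": "linear", "payload": {
            "beta": model.beta.tolist(), "cutoff": model.cutoff,
            "method": model.method, "intercept": model.intercept,
            "degenerate": model.degenerate}}
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    with open(path) as fh:
        doc = json.load(fh)
    p = doc["payload"]
    if doc["type"] == "kme":
        return KMEModel.from_json(json.dumps(p))
    if doc["type"] == "cov_kme":
        return CovariateKMEModel(
            a=np.asarray(p["a"]), b=np.asarray(p["b"]),
            X_train=np.asarray(p["X_train"]), Z_train=np.asarray(p["Z_train"]),
            kernel_g=KernelSpec(**p["kernel_g"]), kernel_c=KernelSpec(**p["kernel_c"]),
            lam=p["lam"], delta=p["delta"], pi_model=p["pi_model"])
    if doc["type"] == "linear":
        return LinearComboModel(beta=np.asarray(p["beta"]), cutoff=p["cutoff"],
                                method=p["method"], intercept=p["intercept"],
                                degenerate=p["degenerate"])
    raise ValueError(f"unknown model type {doc['type']!r}")
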