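"""CSV readers/writers and model configuration.

Data files are long format: one row per level-1 unit with a cluster-id
column, the outcome, the cluster-level covariates C (constant within
cluster, possibly missing), and fully observed x1 (level-1) / x2 (level-2)
columns.  Empty cells, "NA" and "NaN" are read as missing; missing values
are written as empty cells.

A model declaration (YAML or dict) names the columns and interaction terms::

    y: Valence
    cluster: encounter
    c: [IPre, EPre]
    x1: [Q2, Q3, Q4]
    x2: [CT]
    xc_terms: []          # 1-based indices s of X x C_s interactions
    cc_terms: [[1, 2]]    # pairs (s, t), s < t, of C_s x C_t interactions
    center: false         # center covariates at observed-case sample means
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DataSet, HLMSpec

__all__ = [
    "load_model_config",
    "spec_from_config",
    "read_dataset",
    "dataset_to_frame",
    "write_dataset",
    "write_results",
    "read_results",
]

NA_TOKENS = ["", "NA", "NaN", "nan"]


def load_model_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "y" not in cfg or "cluster" not in cfg or "c" not in cfg:
        raise ValueError("model config must declare at least y, cluster and c")
    return cfg


def spec_from_config(cfg: dict) -> HLMSpec:
    c = list(cfg["c"])
    x1 = list(cfg.get("x1", []) or [])
    x2 = list(cfg.get("x2", []) or [])
    return HLMSpec(
        p=len(c),
        q1=len(x1),
        q2=len(x2),
        xc_terms=tuple(cfg.get("xc_terms", []) or []),
        cc_terms=tuple(tuple(t) for t in (cfg.get("cc_terms", []) or [])),
        c_names=tuple(c),
        x1_names=tuple(x1),
        x2_names=tuple(x2),
    )


def read_dataset(path_or_frame, cfg: dict) -> tuple[DataSet, HLMSpec, dict]:
    """Parse a long-format CSV (or DataFrame) into a DataSet.

    Validates that C and x2 are constant within cluster and that X is fully
    observed.  Returns (data, spec, meta); meta reports per-variable missing
    rates and (if requested) the centering constants applied.
    """
    spec = spec_from_config(cfg)
    if isinstance(path_or_frame, (str, Path)):
        df = pd.read_csv(path_or_frame, na_values=NA_TOKENS, keep_default_na=False)
    else:
        df = path_or_frame.copy()
    needed = [cfg["y"], cfg["cluster"], *spec.c_names, *spec.x1_names, *spec.x2_names]
    unknown = [c for c in needed if c not in df.columns]
    if unknown:
        raise ValueError(f"columns not found in data: {unknown}")

    codes, uniques = pd.factorize(df[cfg["cluster"]], sort=True)
    J = len(uniques)
    N = len(df)
    y = df[cfg["y"]].to_numpy(dtype=float)
    y_missing = np.isnan(y)

    def cluster_constant(col: str) -> np.ndarray:
        vals = df[col].to_numpy(dtype=float)
        out = np.full(J, np.nan)
        for j in range(J):
            v = vals[codes == j]
            vv = v[~np.isnan(v)]
            if vv.size and not np.all(vv == vv[0]):
                raise ValueError(
                    f"cluster-level column {col!r} varies within cluster "
                    f"{uniques[j]!r}"
                )
            if np.isnan(v).any() and vv.size:
                raise ValueError(
                    f"cluster-level column {col!r} partially missing within "
                    f"cluster {uniques[j]!r}: cluster-level values must be "
                    "missing for all rows of the cluster or none"
                )
            if vv.size:
                out[j] = vv[0]
        return out

    C = np.column_stack([cluster_constant(c) for c in spec.c_names]) if spec.p else np.zeros((J, 0))
    c_missing = np.isnan(C)
    X1 = df[list(spec.x1_names)].to_numpy(dtype=float).reshape(N, -1)
    if np.isnan(X1).any():
        raise ValueError("level-1 covariates x1 must be fully observed")
    X2 = np.column_stack([cluster_constant(c) for c in spec.x2_names]) if spec.q2 else np.zeros((J, 0))
    if np.isnan(X2).any():
        raise ValueError("level-2 covariates x2 must be fully observed")

    meta: dict = {}
    if cfg.get("center"):
        centers = {}
        for k, name in enumerate(spec.c_names):
            m = float(np.nanmean(np.where(c_missing[:, k], np.nan, C[:, k])))
            C[:, k] -= m
            centers[name] = m
        for k, name in enumerate(spec.x1_names):
            m = float(X1[:, k].mean())
            X1[:, k] -= m
            centers[name] = m
        for k, name in enumerate(spec.x2_names):
            m = float(X2[:, k].mean())
            X2[:, k] -= m
            centers[name] = m
        meta["centers"] = centers

    data = DataSet(
        y=y, y_missing=y_missing, C=C, c_missing=c_missing,
        X1=X1, X2=X2, cluster_index=codes, cluster_ids=np.asarray(uniques),
    )
    meta["missing_rates"] = data.missing_rates()
    return data, spec, meta


def dataset_to_frame(data: DataSet, spec: HLMSpec, y_name="Y", cluster_name="cluster") -> pd.DataFrame:
    """Long-format frame with missing entries as NaN (written as empty cells)."""
    ci = data.cluster_index
    out = {cluster_name: np.asarray(data.cluster_ids)[ci]}
    y = data.y.astype(float).copy()
    y[data.y_missing] = np.nan
    out[y_name] = y
    C = data.C.copy()
    C[data.c_missing] = np.nan
    for k, name in enumerate(spec.c_names):
        out[name] = C[ci, k]
    for k, name in enumerate(spec.x1_names):
        out[name] = data.X1[:, k]
    for k, name in enumerate(spec.x2_names):
        out[name] = data.X2[ci, k]
    return pd.DataFrame(out)


def write_dataset(data: DataSet, spec: HLMSpec, path, **kw) -> None:
    dataset_to_frame(data, spec, **kw).to_csv(path, index=False, na_rep="")


def write_results(results: dict, path) -> None:
    """Serialize a results dictionary (posterior table, diagnostics, metadata).

    DataFrames/Series/ndarrays are converted to JSON-friendly structures;
    floats keep full precision so a read-back equals the written object.
    """

    def convert(obj):
        if isinstance(obj, pd.DataFrame):
            return {"__frame__": True, "index": list(obj.index),
                    "columns": list(obj.columns),
                    "data": obj.to_numpy().tolist()}
        if isinstance(obj, pd.Series):
            return {"__series__": True, "index": list(obj.index), "data": obj.to_numpy().tolist()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(convert(results), fh, indent=1)


def read_results(path) -> dict:
    def restore(obj):
        if isinstance(obj, dict):
            if obj.get("__frame__"):
                return pd.DataFrame(obj["data"], index=obj["index"], columns=obj["columns"])
            if obj.get("__series__"):
                return pd.Series(obj["data"], index=obj["index"])
            return {k: restore(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [restore(v) for v in obj]
        return obj

    with open(path) as fh:
        return restore(json.load(fh))
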