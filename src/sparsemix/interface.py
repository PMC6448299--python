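"""Dataset I/O and run configuration.

Datasets are delimited text with a header.  Categorical variables are coded
1..D_j in files (0-based internally); count regression files carry a
response column ``y``, optional ``offset`` column (entered into the design
matrix as log offset) and covariate columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .priors_weights import PriorConfig, match_priors

__all__ = [
    "CategoricalData", "CountData", "CountRegressionData", "ContinuousData",
    "read_dataset", "write_dataset", "RunConfig", "parse_config",
    "provenance_record",
]

DATASET_TYPES = ("categorical", "counts", "count_regression", "continuous")


@dataclass
class CategoricalData:
    codes: np.ndarray          # (N, r), 0-based
    n_categories: np.ndarray   # (r,)
    columns: list

    @property
    def kernel_data(self):
        return self.codes


@dataclass
class CountData:
    y: np.ndarray

    @property
    def kernel_data(self):
        return self.y


@dataclass
class CountRegressionData:
    y: np.ndarray
    X: np.ndarray              # includes intercept column
    columns: list

    @property
    def kernel_data(self):
        return (self.y, self.X)


@dataclass
class ContinuousData:
    y: np.ndarray

    @property
    def kernel_data(self):
        return self.y


def _parse_error(path, row, msg):
    return ValueError(f"{path}: row {row}: {msg}")


def read_dataset(path, dtype: str, n_categories=None):
    """Read and validate a delimited dataset of the given type."""
    path = Path(path)
    if dtype not in DATASET_TYPES:
        raise ValueError(f"unknown dataset type {dtype!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")

    if dtype == "categorical":
        vals = df.to_numpy()
        for i in range(df.shape[0]):
            for j, col in enumerate(df.columns):
                v = vals[i, j]
                if not float(v).is_integer() or v < 1:
                    raise _parse_error(path, i + 1,
                                       f"non-integer or out-of-range category "
                                       f"{v!r} in column {col!r}")
        codes = df.to_numpy(dtype=int) - 1
        D = (np.asarray(n_categories, dtype=int) if n_categories is not None
             else codes.max(axis=0) + 1)
        D = np.maximum(D, 2)
        bad = np.where(codes >= D[None, :])
        if bad[0].size:
            raise _parse_error(path, int(bad[0][0]) + 1,
                               "category code exceeds declared cardinality")
        return CategoricalData(codes=codes, n_categories=D,
                               columns=list(df.columns))

    if dtype == "counts":
        col = df.columns[0]
        y = df[col].to_numpy(dtype=float)
        bad = np.where((y < 0) | (y != np.floor(y)))[0]
        if bad.size:
            raise _parse_error(path, int(bad[0]) + 1,
                               f"negative or non-integer count {y[bad[0]]!r}")
        return CountData(y=y)

    if dtype == "count_regression":
        if "y" not in df.columns:
            raise ValueError(f"{path}: count_regression needs a 'y' column")
        y = df["y"].to_numpy(dtype=float)
        bad = np.where((y < 0) | (y != np.floor(y)))[0]
        if bad.size:
            raise _parse_error(path, int(bad[0]) + 1, "negative count response")
        cov = df.drop(columns=["y"])
        cols = ["intercept"]
        X = [np.ones(df.shape[0])]
        if "offset" in cov.columns:
            off = cov.pop("offset").to_numpy(dtype=float)
            if np.any(off <= 0):
                raise ValueError(f"{path}: offsets must be positive")
            X.append(np.log(off))
            cols.append("log_offset")
        for c in cov.columns:
            X.append(cov[c].to_numpy(dtype=float))
            cols.append(c)
        return CountRegressionData(y=y, X=np.column_stack(X), columns=cols)

    return ContinuousData(y=df[df.columns[0]].to_numpy(dtype=float))


def write_dataset(path, data) -> None:
    """Inverse of read_dataset on validated data (categorical codes are
    written 1-based)."""
    path = Path(path)
    if isinstance(data, CategoricalData):
        pd.DataFrame(data.codes + 1, columns=data.columns).to_csv(path, index=False)
    elif isinstance(data, CountData):
        pd.DataFrame({"y": data.y.astype(int)}).to_csv(path, index=False)
    elif isinstance(data, CountRegressionData):
        df = pd.DataFrame(data.X[:, 1:], columns=data.columns[1:])
        df.insert(0, "y", data.y.astype(int))
        df.to_csv(path, index=False)
    elif isinstance(data, ContinuousData):
        pd.DataFrame({"y": data.y}).to_csv(path, index=False)
    else:
        raise TypeError(f"unknown dataset object {type(data)!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KERNEL_FOR_TYPE = {
    "lca": "categorical",
    "poisson": "counts",
    "poisson_glm": "count_regression",
    "negbin_glm": "count_regression",
    "skew_normal": "continuous",
    "skew_t": "continuous",
}

_ALLOWED_KEYS = {"dataset", "kernel", "family", "K", "precision_prior",
                 "match_from", "burnin", "iters", "seed", "thin", "out",
                 "kernel_hyper"}


@dataclass
class RunConfig:
    dataset_path: str
    dataset_type: str
    kernel: str
    prior: PriorConfig
    n_burnin: int = 8000
    n_iter: int = 8000
    seed: int | None = None
    thin: int = 1
    outdir: str = "."
    raw: dict = field(default_factory=dict)


def _prior_from_spec(spec, family, K, kernel_hyper):
    """Parse a precision-prior spec: 'a,b' (Gamma), 'fixed:v', 'uniform:u'
    or a mapping."""
    kwargs = dict(family=family, K=K, kernel_hyper=kernel_hyper)
    if spec is None:
        if family == "sparse_finite":
            return PriorConfig(precision_prior="gamma", shape=1.0, rate=200.0,
                               **kwargs)
        return PriorConfig(precision_prior="gamma", shape=2.0, rate=4.0,
                           **kwargs)
    if isinstance(spec, dict):
        return PriorConfig(**{**kwargs, **spec})
    spec = str(spec)
    if spec.startswith("fixed:"):
        return PriorConfig(precision_prior="fixed",
                           value=float(spec.split(":", 1)[1]), **kwargs)
    if spec.startswith("uniform:"):
        return PriorConfig(precision_prior="uniform",
                           upper=float(spec.split(":", 1)[1]), **kwargs)
    a, b = (float(x) for x in spec.split(","))
    return PriorConfig(precision_prior="gamma", shape=a, rate=b, **kwargs)


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration (strict keys)."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    ds = cfg.get("dataset")
    if not isinstance(ds, dict) or "path" not in ds:
        raise ValueError(f"{path}: 'dataset' must be a mapping with 'path'")
    kernel = cfg.get("kernel", "lca")
    if kernel not in _KERNEL_FOR_TYPE:
        raise ValueError(f"{path}: unknown kernel {kernel!r}")
    ds_type = ds.get("type", _KERNEL_FOR_TYPE[kernel])
    if ds_type != _KERNEL_FOR_TYPE[kernel]:
        raise ValueError(f"{path}: kernel {kernel!r} needs dataset type "
                         f"{_KERNEL_FOR_TYPE[kernel]!r}, got {ds_type!r}")
    family = {"sfm": "sparse_finite", "sparse_finite": "sparse_finite",
              "dpm": "dirichlet_process",
              "dirichlet_process": "dirichlet_process"}.get(
                  cfg.get("family", "sfm"))
    if family is None:
        raise ValueError(f"{path}: unknown family {cfg.get('family')!r}")
    K = int(cfg.get("K", 10))
    kernel_hyper = dict(cfg.get("kernel_hyper") or {})

    match = cfg.get("match_from")
    if match is not None:
        src = {"sfm": "sparse_finite", "dpm": "dirichlet_process"}.get(
            match.get("family"), match.get("family"))
        a, b = float(match["a"]), float(match["b"])
        if src == family:
            raise ValueError(f"{path}: match_from family equals target family")
        direction = "dpm_to_sfm" if family == "sparse_finite" else "sfm_to_dpm"
        a, b = match_priors(direction, a, b, K)
        prior = PriorConfig(family=family, K=K, precision_prior="gamma",
                            shape=a, rate=b, kernel_hyper=kernel_hyper)
    else:
        prior = _prior_from_spec(cfg.get("precision_prior"), family, K,
                                 kernel_hyper)

    return RunConfig(
        dataset_path=str(ds["path"]), dataset_type=ds_type, kernel=kernel,
        prior=prior, n_burnin=int(cfg.get("burnin", 8000)),
        n_iter=int(cfg.get("iters", 8000)), seed=cfg.get("seed"),
        thin=int(cfg.get("thin", 1)), outdir=str(cfg.get("out", ".")),
        raw=cfg)


def provenance_record(config: RunConfig | dict, seed) -> dict:
    """Machine-readable provenance: config hash, seed, package version."""
    from . import __version__

    raw = config.raw if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": seed, "sparsemix_version": __version__,
            "numpy_version": np.__version__}
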