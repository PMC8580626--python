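"""Tabular I/O, normalization, and a seeded synthetic benchmark generator.

The synthetic generator plants the situation the detector assumes: the
bulk of the samples lie near a low-dimensional linear manifold (clustered
Gaussian latent factors pushed through a random linear map, plus isotropic
noise), while a small fraction of outliers are drawn off that structure —
uniformly in the normals' bounding box, or with grossly inflated noise.
A kNN graph over such data captures the manifold neighbourhoods, and the
factorization reconstructs on-manifold samples far better than the planted
outliers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "SynthConfig",
    "load_tabular",
    "normalize",
    "generate_synthetic",
    "write_csv",
]


@dataclass
class DataMatrix:
    """Feature-by-sample matrix with names and optional outlier labels."""

    X: np.ndarray  # (m, n), float, finite
    feature_names: list
    sample_ids: list
    labels: np.ndarray | None = None  # (n,), values in {0, 1}
    clusters: np.ndarray | None = None  # synthetic provenance, normals only

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


@dataclass
class SynthConfig:
    """Settings for the planted-outlier generator.

    Defaults: 285 normals + 15 outliers (5% contamination) in 20 ambient
    dimensions on a rank-3 manifold with 3 clusters and mild noise.
    """

    n_normal: int = 285
    n_outlier: int = 15
    m: int = 20
    latent_dim: int = 3
    n_clusters: int = 3
    noise_sd: float = 0.1
    outlier_mode: str = "uniform_box"
    seed: int = 0

    def __post_init__(self):
        if self.n_normal < 1 or self.n_outlier < 0:
            raise ValueError("need n_normal >= 1 and n_outlier >= 0")
        if not 0 < self.latent_dim < self.m:
            raise ValueError("latent_dim must be in (0, m)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.outlier_mode not in ("uniform_box", "inflated_noise"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")


def load_tabular(path, label_column: str | None = None) -> DataMatrix:
    """Load a samples-as-rows CSV into feature-by-sample orientation.

    Rows with missing values are dropped; categorical (non-numeric) feature
    columns are one-hot encoded; an optional binary label column is split
    off and never enters the features.
    """
    df = pd.read_csv(path)
    df = df.dropna(axis=0, how="any").reset_index(drop=True)
    if df.shape[0] == 0:
        raise ValueError("no complete rows left after dropping missing values")

    sample_ids = None
    if df.columns.size and df.columns[0] == "sample_id":
        sample_ids = [str(s) for s in df.pop("sample_id")]

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in CSV")
        raw = df.pop(label_column).to_numpy()
        labels = np.asarray(raw)
        try:
            labels = labels.astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"label column {label_column!r} is not numeric") from exc
        if not np.isin(labels, (0, 1)).all():
            raise ValueError(f"label column {label_column!r} must be binary 0/1")

    cat_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if cat_cols:
        df = pd.get_dummies(df, columns=cat_cols, dtype=float)
    for c in df.columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"column {c!r} is not numeric after encoding")

    X = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in loaded data")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X.shape[1])]
    return DataMatrix(
        X=X,
        feature_names=[str(c) for c in df.columns],
        sample_ids=sample_ids,
        labels=labels,
    )


def normalize(X: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Per-feature scaling: min-max to [0, 1] (default) or z-score.

    Constant features map to zero under both methods.
    """
    X = np.asarray(X, dtype=float)
    if method == "minmax":
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.zeros_like(X)
        nonconst = span[:, 0] > 0
        out[nonconst] = (X[nonconst] - lo[nonconst]) / span[nonconst]
        return out
    if method == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        out = np.zeros_like(X)
        nonconst = sd[:, 0] > 0
        out[nonconst] = (X[nonconst] - mu[nonconst]) / sd[nonconst]
        return out
    raise ValueError(f"unknown normalization method {method!r}")


def generate_synthetic(config: SynthConfig | None = None, **kwargs) -> DataMatrix:
    """Low-rank clustered normals with planted off-manifold outliers.

    Normals: latent cluster centres ~ N(0, 3^2 I) in ``latent_dim``
    dimensions; points ~ N(centre, I); mapped to ambient space by a fixed
    random ``m x latent_dim`` matrix (entries N(0, 1/latent_dim^(1/2)))
    plus N(0, noise_sd^2) isotropic noise.  Outliers: uniform draws from
    the normals' ambient bounding box (``uniform_box``) or on-manifold
    points with 10x noise (``inflated_noise``).  Sample order is shuffled;
    everything is determined by the seed.
    """
    cfg = config or SynthConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)

    centers = rng.normal(0.0, 3.0, size=(cfg.n_clusters, cfg.latent_dim))
    assign = rng.integers(0, cfg.n_clusters, size=cfg.n_normal)
    Z = centers[assign] + rng.standard_normal((cfg.n_normal, cfg.latent_dim))
    A = rng.standard_normal((cfg.m, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)
    normals = A @ Z.T + cfg.noise_sd * rng.standard_normal((cfg.m, cfg.n_normal))

    if cfg.n_outlier > 0:
        if cfg.outlier_mode == "uniform_box":
            lo = normals.min(axis=1, keepdims=True)
            hi = normals.max(axis=1, keepdims=True)
            outliers = lo + (hi - lo) * rng.random((cfg.m, cfg.n_outlier))
        else:  # inflated_noise
            a_out = rng.integers(0, cfg.n_clusters, size=cfg.n_outlier)
            Zo = centers[a_out] + rng.standard_normal((cfg.n_outlier, cfg.latent_dim))
            outliers = A @ Zo.T + 10.0 * cfg.noise_sd * rng.standard_normal(
                (cfg.m, cfg.n_outlier)
            )
        X = np.concatenate([normals, outliers], axis=1)
        labels = np.concatenate(
            [np.zeros(cfg.n_normal, dtype=int), np.ones(cfg.n_outlier, dtype=int)]
        )
        clusters = np.concatenate([assign, np.full(cfg.n_outlier, -1)])
    else:
        X, labels, clusters = normals, np.zeros(cfg.n_normal, dtype=int), assign.copy()

    perm = rng.permutation(X.shape[1])
    X = X[:, perm]
    labels = labels[perm]
    clusters = clusters[perm]

    n = X.shape[1]
    return DataMatrix(
        X=X,
        feature_names=[f"f{i:02d}" for i in range(cfg.m)],
        sample_ids=[f"s{j:04d}" for j in range(n)],
        labels=labels,
        clusters=clusters,
    )


def write_csv(dm: DataMatrix, path, config: SynthConfig | None = None) -> None:
    """Samples-as-rows CSV (+`.json` sidecar with the generator config)."""
    df = pd.DataFrame(dm.X.T, columns=dm.feature_names, index=dm.sample_ids)
    if dm.labels is not None:
        df["outlier"] = dm.labels
    df.to_csv(path, index_label="sample_id")
    if config is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(config), fh, indent=2)
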