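"""Feature scaling to (−1, 1) and PCA projection, fit on training data only.

PCA is scale-sensitive, so every feature is first min-max mapped onto
(−1, 1) using the *training* extrema; test rows transformed with those
extrema may fall outside the interval and are deliberately not clipped.
The projection keeps the top ``q`` principal axes of the scaled training
features (q = 2, 3 or 4) with a deterministic sign convention: the
largest-magnitude loading of each axis is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class ScalerParams:
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min for every feature")


@dataclass
class PCAParams:
    means: np.ndarray          # per-feature training means (on the scaled table)
    loadings: np.ndarray       # (n_features × q), orthonormal columns
    explained_variance_ratio: np.ndarray  # all n_features components
    q: int


def fit_scaler(X: np.ndarray) -> ScalerParams:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty feature table")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the scaler")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in feature table")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaler(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    span = params.maxs - params.mins
    constant = span == 0
    if np.any(constant):
        warnings.warn("constant feature(s) mapped to 0")
    safe = np.where(constant, 1.0, span)
    out = 2.0 * (X - params.mins) / safe - 1.0
    out[:, constant] = 0.0
    return out


def fit_pca(X: np.ndarray, q: int) -> PCAParams:
    """Fit a full PCA on the scaled training table and keep the top q axes."""
    X = np.asarray(X, dtype=float)
    if q not in (2, 3, 4):
        raise ValueError("q must be 2, 3 or 4")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many rows as features")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if q > rank:
        raise ValueError(f"q={q} exceeds data rank {rank}")
    loadings = pca.components_[:q].T.copy()   # (d × q)
    # Deterministic sign: largest-magnitude loading of each axis positive.
    for c in range(q):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    return PCAParams(
        means=pca.mean_.copy(),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        q=q,
    )


def apply_pca(X: np.ndarray, params: PCAParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.means) @ params.loadings


def fit_transform_pipeline(
    X_train: np.ndarray, q: int
) -> tuple[np.ndarray, ScalerParams, PCAParams]:
    """Scale-then-project the training table; returns transformed rows + params."""
    scaler = fit_scaler(X_train)
    Xs = apply_scaler(X_train, scaler)
    pca = fit_pca(Xs, q)
    return apply_pca(Xs, pca), scaler, pca


def transform_pipeline(X: np.ndarray, scaler: ScalerParams, pca: PCAParams) -> np.ndarray:
    return apply_pca(apply_scaler(X, scaler), pca)


def params_to_json(scaler: ScalerParams, pca: PCAParams) -> str:
    return json.dumps({
        "mins": scaler.mins.tolist(),
        "maxs": scaler.maxs.tolist(),
        "means": pca.means.tolist(),
        "loadings": pca.loadings.tolist(),
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "q": pca.q,
    })


def params_from_json(doc: str) -> tuple[ScalerParams, PCAParams]:
    d = json.loads(doc)
    scaler = ScalerParams(mins=np.array(d["mins"]), maxs=np.array(d["maxs"]))
    pca = PCAParams(
        means=np.array(d["means"]),
        loadings=np.array(d["loadings"]),
        explained_variance_ratio=np.array(d["explained_variance_ratio"]),
        q=int(d["q"]),
    )
    return scaler, pca
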