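"""Training-anchored feature normalization, PCA reduction and projection,
plus the Euler-number quality normalization.

All statistics (per-feature mean/SD, component loadings) are estimated on
the training cohort once and then *applied* to out-of-sample scans; test
data never contribute to the normalization. This anchoring is what makes
brain-age predictions on repeated-session data comparable across sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FitError, InputError, SchemaError

__all__ = [
    "normalize_euler",
    "ScalerModel",
    "fit_feature_scaler",
    "apply_scaler",
    "PCAModel",
    "fit_pca",
    "project",
]


def normalize_euler(raw):
    """Normalize raw average Euler numbers: ``-ln(-raw + 1)``.

    Raw Euler numbers of reconstructed cortical surfaces are at most 2 and
    heavily left-skewed (large negative values for poor scans); the log
    transform maps (-inf, 1) bijectively onto the real line, is strictly
    increasing, and fixes 0. Scalar in, scalar out.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(np.isnan(arr)):
        raise InputError("raw Euler values contain NaN")
    if np.any(arr >= 1):
        raise InputError(
            f"raw Euler values must be < 1 (got max {np.max(arr)}): -ln(-raw+1) undefined"
        )
    out = -np.log1p(-arr)
    return float(out) if np.isscalar(raw) else out


@dataclass(frozen=True)
class ScalerModel:
    """Per-feature training mean/SD (sample SD, n-1 denominator)."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.asarray(self.sds) <= 0):
            raise FitError("ScalerModel SDs must be positive for retained features")


def fit_feature_scaler(train: pd.DataFrame) -> ScalerModel:
    """Estimate per-feature mean and sample SD on the training matrix.

    Zero-variance features are dropped with a warning (they carry no
    information and would divide by zero); an error is raised only when no
    feature survives.
    """
    if train.shape[0] < 2:
        raise InputError("need at least 2 rows to estimate feature SDs")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    zero = sds[sds == 0].index.tolist()
    if len(zero) == train.shape[1]:
        raise FitError(f"all features have zero variance: {zero[:10]}...")
    if zero:
        warnings.warn(
            f"dropping {len(zero)} zero-variance feature(s): {zero[:10]}",
            stacklevel=2,
        )
    keep = [c for c in train.columns if c not in set(zero)]
    return ScalerModel(
        feature_names=keep,
        means=means[keep].to_numpy(),
        sds=sds[keep].to_numpy(),
        dropped=zero,
    )


def apply_scaler(X: pd.DataFrame, scaler: ScalerModel) -> pd.DataFrame:
    """Standardize with *training* statistics only: ``(x - mean) / sd``.

    Columns the scaler dropped at fit time are silently dropped here too;
    a retained feature missing from ``X`` is a schema error.
    """
    missing = [c for c in scaler.feature_names if c not in X.columns]
    if missing:
        raise SchemaError(f"feature matrix is missing scaler features: {missing[:10]}")
    vals = X[scaler.feature_names].to_numpy(dtype=float)
    return pd.DataFrame(
        (vals - scaler.means) / scaler.sds, index=X.index, columns=scaler.feature_names
    )


@dataclass(frozen=True)
class PCAModel:
    """SVD-based principal components of the standardized training matrix.

    ``loadings`` is features x components with orthonormal columns; the sign
    of each column is fixed so its largest-magnitude entry is positive.
    ``explained_variance_ratio`` covers the retained components (fractions
    of the total training variance, non-increasing).
    """

    feature_names: list[str]
    loadings: np.ndarray
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(scaled: pd.DataFrame, max_components: int) -> PCAModel:
    """Principal components of an (already standardized) training matrix.

    Deterministic thin SVD; no re-centering is performed, so the caller is
    responsible for passing scaler output.
    """
    n, p = scaled.shape
    if n < 2:
        raise InputError("need at least 2 rows for PCA")
    limit = min(n - 1, p)
    if not 1 <= max_components <= limit:
        raise InputError(
            f"max_components must be in [1, {limit}] for a {n}x{p} matrix, got {max_components}"
        )
    u, s, vt = np.linalg.svd(scaled.to_numpy(dtype=float), full_matrices=False)
    total_var = float(np.sum(s**2))
    loadings = vt[:max_components].T.copy()
    # sign convention: largest-|entry| of each loading is positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(max_components)])
    flip[flip == 0] = 1.0
    loadings *= flip
    return PCAModel(
        feature_names=list(scaled.columns),
        loadings=loadings,
        singular_values=s[:max_components].copy(),
        explained_variance_ratio=(s[:max_components] ** 2) / total_var,
        n_samples=n,
    )


def project(X: pd.DataFrame, scaler: ScalerModel, pca: PCAModel, k: int) -> pd.DataFrame:
    """Score matrix of ``X`` on the first ``k`` training components.

    Standardizes with the training scaler, then multiplies by the loadings —
    an exact linear map anchored entirely in training statistics. ``k = 0``
    returns an empty frame with matching rows.
    """
    if not 0 <= k <= pca.n_components:
        raise InputError(f"k must be in [0, {pca.n_components}], got {k}")
    scaled = apply_scaler(X, scaler)
    if list(scaled.columns) != pca.feature_names:
        scaled = scaled[pca.feature_names]
    scores = scaled.to_numpy() @ pca.loadings[:, :k]
    return pd.DataFrame(
        scores, index=X.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
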