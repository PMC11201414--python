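"""Statistical characterisation of extracted feature sets.

Per-class summaries mirror the usual texture-feature report: sample mean,
unbiased variance, standardized skewness, *excess* kurtosis (Gaussian -> 0),
intra-class Pearson correlation, and the first canonical correlation between
class feature blocks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cholesky, solve_triangular, svd

__all__ = [
    "ClassFeatureSummary",
    "moments",
    "pearson",
    "canonical_correlation",
    "summarize_features",
]


@dataclasses.dataclass(frozen=True)
class ClassFeatureSummary:
    class_label: str
    method: str
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    pcc: float
    cca: float


def moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, unbiased variance, skewness, excess kurtosis).

    Skewness/kurtosis are the plain standardized third/fourth central moments
    (kurtosis Gaussian-relative); both are NaN for zero-variance input.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var == 0.0:
        return mean, 0.0, float("nan"), float("nan")
    skew = float(sps.skew(x, bias=True))
    kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    return mean, var, skew, kurt


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def canonical_correlation(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8) -> float:
    """First canonical correlation between blocks X (n x p) and Y (n x q).

    Computed by SVD of the whitened cross-covariance
    ``Sxx^{-1/2} Sxy Syy^{-1/2}``; rank-deficient blocks are ridge-regularised
    with a warning.  Invariant under separate invertible affine transforms of
    each block; reduces to |pearson| for p = q = 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 1-D or 2-D")
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= max(X.shape[1], Y.shape[1]):
        raise ValueError("need more samples than variables in either block")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc / (n - 1)
    syy = Yc.T @ Yc / (n - 1)
    sxy = Xc.T @ Yc / (n - 1)

    def _chol(s: np.ndarray, name: str) -> np.ndarray:
        try:
            return cholesky(s, lower=True)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"{name} block is rank-deficient; ridge-regularising",
                RuntimeWarning, stacklevel=3,
            )
            scale = max(float(np.trace(s)) / s.shape[0], 1.0)
            return cholesky(s + ridge * scale * np.eye(s.shape[0]), lower=True)

    lx = _chol(sxx, "X")
    ly = _chol(syy, "Y")
    k = solve_triangular(lx, sxy, lower=True)
    k = solve_triangular(ly, k.T, lower=True).T
    s = svd(k, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def summarize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Per-(method, class) summary of a feature table.

    ``features`` has columns image_id, label, method, v1..vk.  Moments and the
    intra-class PCC are computed on the pooled feature values of the class
    (PCC between the two halves of the class's stacked feature columns); CCA
    is computed between the two class feature blocks of the same method and
    reported on both class rows.
    """
    value_cols = [c for c in features.columns if c.startswith("v")]
    if not value_cols:
        raise ValueError("no feature value columns (v1..vk) found")
    rows = []
    for method, per_method in features.groupby("method", sort=False):
        blocks = {
            lab: grp[value_cols].to_numpy(dtype=float)
            for lab, grp in per_method.groupby("label", sort=False)
        }
        labels = list(blocks)
        cca = float("nan")
        if len(labels) == 2:
            a, b = blocks[labels[0]], blocks[labels[1]]
            n = min(a.shape[0], b.shape[0])
            if n > len(value_cols):
                cca = canonical_correlation(a[:n], b[:n])
        for lab, block in blocks.items():
            pooled = block.ravel()
            mean, var, skew, kurt = moments(pooled)
            half = len(value_cols) // 2
            if half >= 1 and len(value_cols) >= 2:
                pcc = pearson(
                    block[:, :half].ravel(), block[:, half : 2 * half].ravel()
                )
            else:
                pcc = float("nan")
            rows.append(
                ClassFeatureSummary(lab, method, mean, var, skew, kurt, pcc, cca)
            )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
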