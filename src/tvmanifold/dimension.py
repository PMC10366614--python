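"""Intrinsic dimension estimation for tvFC window clouds.

Two estimators are provided. TwoNN uses the distribution of the ratio
mu = r2/r1 of each point's second- to first-nearest-neighbor distances: under
a locally uniform Poisson model mu follows a Pareto law with CDF
F(mu) = 1 - mu^(-d), so d is recovered as the slope of -log(1 - F) against
log mu in a least-squares fit through the origin, computed on the smallest
90% of ratios (the method's convention for robustness against boundary and
outlier points; plain truncated-sample MLE is biased upward by the
truncation). lPCA counts the principal components needed to
reach a cumulative explained-variance threshold (default 0.95), either over
the whole sample (global) or per-sample over k-NN neighborhoods (local).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .containers import TvfcMatrix

DEFAULT_LOCAL_K_GRID = [50, 75, 100, 125, 150, 175, 200]


@dataclass
class IdEstimate:
    estimator: str  # {"twoNN", "lPCA"}
    scope: str  # {"global", "local"}
    value: float | np.ndarray  # scalar (global) or per-sample vector (local)
    n_samples: int
    k: int | None = None  # neighborhood size (local only)

    @property
    def mean(self) -> float:
        return float(np.mean(self.value))


def twonn_id(samples: np.ndarray, discard_fraction: float = 0.1) -> float:
    """TwoNN global intrinsic-dimension estimate.

    Duplicate points (zero first-neighbor distance) are dropped with a
    warning; the largest ``discard_fraction`` of distance ratios are excluded
    from the likelihood.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if n < 20:
        raise ValueError("TwoNN needs at least 20 points")
    nn = NearestNeighbors(n_neighbors=3).fit(samples)
    dist, _ = nn.kneighbors(samples)
    r1, r2 = dist[:, 1], dist[:, 2]
    ok = r1 > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} duplicate points", stacklevel=2)
    if not ok.any():
        raise ValueError("all points are duplicated; TwoNN undefined")
    mu = np.sort(r2[ok] / r1[ok])
    n_used = len(mu)
    n_keep = max(int(np.floor(n_used * (1.0 - discard_fraction))), 2)
    x = np.log(mu[:n_keep])
    # empirical CDF over the full (pre-discard) ratio sample
    f = np.arange(1, n_keep + 1) / n_used
    y = -np.log(1.0 - f)
    denom = float(np.dot(x, x))
    if denom <= 0:
        raise ValueError("degenerate neighbor-ratio distribution")
    return float(np.dot(x, y) / denom)


def _pca_count(samples: np.ndarray, threshold: float) -> int:
    x = samples - samples.mean(axis=0, keepdims=True)
    # eigenvalues of the covariance via singular values; robust to n < p
    sv = np.linalg.svd(x, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        return 1
    frac = np.cumsum(var) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def lpca_id(
    samples: np.ndarray,
    scope: str = "global",
    k: int = 50,
    threshold: float = 0.95,
) -> IdEstimate:
    """PCA-based intrinsic dimension: components reaching ``threshold``
    cumulative explained variance; local scope evaluates each sample's k-NN
    neighborhood separately."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if scope == "global":
        return IdEstimate("lPCA", "global", float(_pca_count(samples, threshold)), n)
    if scope != "local":
        raise ValueError("scope must be 'global' or 'local'")
    if k < 5:
        raise ValueError("local lPCA needs k >= 5")
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(samples)
    _, idx = nn.kneighbors(samples)
    values = np.array(
        [_pca_count(samples[idx[i]], threshold) for i in range(n)], dtype=float
    )
    return IdEstimate("lPCA", "local", values, n, k=k)


def twonn_local_id(samples: np.ndarray, k: int = 50) -> IdEstimate:
    """Per-sample TwoNN over k-NN neighborhoods (k >= 20)."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    k = min(k, n - 1)
    if k < 20:
        raise ValueError("local TwoNN needs k >= 20")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(samples)
    _, idx = nn.kneighbors(samples)
    values = np.array([twonn_id(samples[idx[i]]) for i in range(n)])
    return IdEstimate("twoNN", "local", values, n, k=k)


def estimate_id(
    tvfc: TvfcMatrix,
    estimator: str = "twonn",
    scope: str = "global",
    k: int = 100,
    window_subset: list[str] | None = None,
) -> IdEstimate:
    """Estimate the intrinsic dimension of a tvFC window cloud.

    ``window_subset`` restricts to windows with the given labels (e.g., one
    task's homogeneous windows); windows are the points, connections the
    ambient coordinates.
    """
    mat = tvfc.window_subset(window_subset) if window_subset else tvfc
    pts = mat.values.T
    if pts.shape[0] < 20:
        raise ValueError(
            f"window subset has only {pts.shape[0]} windows; need at least 20"
        )
    est = estimator.lower()
    if est == "twonn":
        if scope == "global":
            return IdEstimate("twoNN", "global", twonn_id(pts), pts.shape[0])
        return twonn_local_id(pts, k=k)
    if est == "lpca":
        return lpca_id(pts, scope=scope, k=k)
    raise ValueError("estimator must be 'twonn' or 'lpca'")
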