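"""Explicit RBF kernel feature maps (Nyström-style center sampling).

A sample ``x`` is mapped to its vector of similarities
``K(x, c_j) = exp(-||x - c_j||² / (2σ²))`` against ``c`` centers drawn
without replacement from the training rows.  The bandwidth σ is estimated
from the sample-to-center Euclidean distances by either the median or a
percentile rule (exact zeros — self-distances — are excluded first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._validation import ValidationError, as_2d

__all__ = ["KernelConfig", "KernelMap", "sample_centers", "estimate_sigma", "rbf_transform", "fit_kernel_map"]


@dataclass
class KernelConfig:
    n_centers: int
    bandwidth_rule: str = "median"  # "median" or "percentile"
    percentile_q: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_centers < 1:
            raise ValidationError("n_centers must be >= 1")
        if self.bandwidth_rule not in ("median", "percentile"):
            raise ValidationError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if not (0 < self.percentile_q <= 100):
            raise ValidationError("percentile_q must be in (0, 100]")


@dataclass
class KernelMap:
    """Sampled centers plus the bandwidth of the RBF map."""

    centers: np.ndarray
    sigma: float | None
    config: KernelConfig


def sample_centers(X_train, config: KernelConfig) -> KernelMap:
    """Draw ``config.n_centers`` distinct training rows as kernel centers."""
    X = as_2d(X_train, "X_train")
    n = X.shape[0]
    if config.n_centers > n:
        raise ValidationError(f"n_centers={config.n_centers} exceeds n_train={n}")
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(n, size=config.n_centers, replace=False)
    return KernelMap(centers=X[idx].copy(), sigma=None, config=config)


def estimate_sigma(distances, rule: str = "median", q: float = 50.0) -> float:
    """Quantile-based bandwidth: median or q-th percentile of nonzero distances.

    Percentiles use linear interpolation between closest order statistics.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValidationError("empty distance collection")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValidationError("distances must be finite and nonnegative")
    d = d[d > 0]
    if d.size == 0:
        raise ValidationError("all distances are zero: degenerate data")
    if rule == "median":
        q = 50.0
    elif rule != "percentile":
        raise ValidationError(f"unknown bandwidth rule {rule!r}")
    return float(np.percentile(d, q))


def rbf_transform(X, kmap: KernelMap) -> np.ndarray:
    """n×c similarity matrix ``exp(-||x_i - c_j||² / (2σ²))``."""
    X = as_2d(X, "X")
    if kmap.sigma is None or kmap.sigma <= 0:
        raise ValidationError("kernel map has no positive bandwidth")
    if X.shape[1] != kmap.centers.shape[1]:
        raise ValidationError(
            f"feature count mismatch: X has {X.shape[1]}, centers have {kmap.centers.shape[1]}"
        )
    sq = cdist(X, kmap.centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * kmap.sigma**2))


def fit_kernel_map(X_train, config: KernelConfig) -> KernelMap:
    """Sample centers and set σ from the training sample-to-center distances."""
    kmap = sample_centers(X_train, config)
    d = cdist(as_2d(X_train), kmap.centers)
    kmap.sigma = estimate_sigma(d, rule=config.bandwidth_rule, q=config.percentile_q)
    return kmap
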