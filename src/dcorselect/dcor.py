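r"""Distance correlation between single features and a target.

Distance correlation (dCor) is a measure of statistical dependence built
from pairwise Euclidean distance matrices.  Unlike the Pearson coefficient
it is zero if and only if the two variables are independent, so it detects
non-linear and non-monotonic relationships — the property the selection
pipelines in this package are built around.

For two univariate samples ``x`` and ``y`` of common length ``n`` the
estimator used here is the plain V-statistic:

1. form the distance matrices ``A_ik = |x_i - x_k|`` and
   ``B_ik = |y_i - y_k|``;
2. double-center each matrix (subtract row and column means, add back the
   grand mean);
3. the squared distance covariance is
   ``V²(x, y) = (1/n²) Σ_ik Ã_ik · B̃_ik`` and

   ``dCor(x, y) = V²(x, y) / (sqrt(V²(x) · V²(y)) + ε)``

with a small ``ε`` (default 1e-10) guarding the division.  When the
numerator is exactly zero — e.g. one input is constant — the result is 0.

The V-statistic is biased upward at small ``n`` (independent samples give a
small positive value rather than 0); no U-statistic correction is applied
because the selection pipelines only consume the ranking, for which the
bias is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validation import ValidationError, as_1d, as_2d

DEFAULT_EPSILON = 1e-10

__all__ = [
    "DEFAULT_EPSILON",
    "DCorScores",
    "pairwise_distance_matrix",
    "double_center",
    "distance_covariance_sq",
    "distance_correlation",
    "score_features",
]


@dataclass
class DCorScores:
    """Per-feature distance-correlation scores, aligned to column order."""

    scores: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")

    def __len__(self) -> int:
        return self.scores.size

    def top_k(self, k: int) -> np.ndarray:
        """Indices of the ``k`` highest scores, ties broken by lower index."""
        if k <= 0 or k > len(self):
            raise ValidationError(f"k={k} out of range for {len(self)} scores")
        # stable sort on negated scores keeps ascending-index tie order
        order = np.argsort(-self.scores, kind="stable")
        return order[:k]


def pairwise_distance_matrix(x) -> np.ndarray:
    """n×n matrix of absolute differences ``|x_i - x_k|``."""
    v = as_1d(x, "x")
    return np.abs(v[:, None] - v[None, :])


def double_center(D) -> np.ndarray:
    """Subtract row/column means and add back the grand mean.

    The result has (numerically) zero row and column sums.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    row = D.mean(axis=1, keepdims=True)
    col = D.mean(axis=0, keepdims=True)
    grand = D.mean()
    return D - row - col + grand


def distance_covariance_sq(A, B) -> float:
    """Squared distance covariance ``(1/n²) Σ Ã_ik B̃_ik`` of two centered matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"centered matrices disagree in shape: {A.shape} vs {B.shape}")
    n = A.shape[0]
    return float((A * B).sum() / (n * n))


def distance_correlation(x, y, epsilon: float = DEFAULT_EPSILON) -> float:
    """dCor(x, y) in [0, 1] with the ε-guarded normalization."""
    xv = as_1d(x, "x")
    yv = as_1d(y, "y")
    if xv.size != yv.size:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise ValidationError("need at least 2 observations")
    A = double_center(pairwise_distance_matrix(xv))
    B = double_center(pairwise_distance_matrix(yv))
    vxy = distance_covariance_sq(A, B)
    if vxy <= 0.0:
        return 0.0
    vx = distance_covariance_sq(A, A)
    vy = distance_covariance_sq(B, B)
    return float(vxy / (np.sqrt(vx * vy) + epsilon))


def score_features(X, y, epsilon: float = DEFAULT_EPSILON) -> DCorScores:
    """dCor of each column of ``X`` against ``y``, in column order.

    The target's centered distance matrix is computed once and reused
    across columns; each score is identical to an independent
    :func:`distance_correlation` call on that column.
    """
    Xm = as_2d(X, "X")
    yv = as_1d(y, "y")
    if Xm.shape[0] != yv.size:
        raise ValidationError(f"X has {Xm.shape[0]} rows but y has {yv.size}")
    if Xm.shape[0] < 2:
        raise ValidationError("need at least 2 rows")
    if not np.all(np.isfinite(Xm)):
        raise ValidationError("X contains non-finite entries")
    B = double_center(pairwise_distance_matrix(yv))
    vy = distance_covariance_sq(B, B)
    scores = np.empty(Xm.shape[1])
    for j in range(Xm.shape[1]):
        A = double_center(pairwise_distance_matrix(Xm[:, j]))
        vxy = distance_covariance_sq(A, B)
        if vxy <= 0.0:
            scores[j] = 0.0
            continue
        vx = distance_covariance_sq(A, A)
        scores[j] = vxy / (np.sqrt(vx * vy) + epsilon)
    return DCorScores(scores=scores, epsilon=epsilon)
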