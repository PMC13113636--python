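"""Adaptive weighting schemes driven by distance-correlation scores.

Three mechanisms are provided:

* **inverse penalty** — ``w_j = 1 / (dCor_j + 0.01)``.  Counterintuitively,
  moderately dependent features receive the *larger* multiplier (dCor 0.5 →
  ≈2) while near-perfect features are left at ≈1, which pulls the kernel's
  input metric toward a diverse, less collinear subset instead of a
  redundant high-dependence cluster.
* **proportional (squared) weights** — ``w_j = dCor_j²``, normalized to
  mean 1.  Amplifies strong features (0.9 → 0.81 vs 0.3 → 0.09, a 9×
  spread); the conventional direction, kept as the contrast case.
* **center importance** — scores a kernel center by its proximity to
  high-dependence features: ``importance(c_i) = Σ_j dCor_j / (|c_ij| + 0.1)``,
  applied to kernel-matrix columns after the transform.

Plus the hybrid split used by the direct+kernel pipeline (top scorers kept
raw, the next band routed through the kernel map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validation import ValidationError, as_2d
from .dcor import DCorScores
from .kernel import KernelMap

__all__ = [
    "WeightVector",
    "inverse_penalty",
    "proportional_weights",
    "apply_column_weights",
    "center_importance",
    "hybrid_split",
]

PENALTY_OFFSET = 0.01
IMPORTANCE_OFFSET = 0.1


@dataclass
class WeightVector:
    weights: np.ndarray
    scheme: str

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValidationError("weights must be positive and finite")

    def __len__(self) -> int:
        return self.weights.size

    def to_text(self, path, names=None) -> None:
        """Two-column audit file: feature id, weight."""
        names = names if names is not None else [f"f{j}" for j in range(len(self))]
        with open(path, "w") as fh:
            for name, w in zip(names, self.weights):
                fh.write(f"{name}\t{w:.12g}\n")


def _scores_array(scores) -> np.ndarray:
    s = scores.scores if isinstance(scores, DCorScores) else np.asarray(scores, dtype=float)
    return np.asarray(s, dtype=float)


def inverse_penalty(scores) -> WeightVector:
    """``1 / (score + 0.01)`` — strictly decreasing in the score."""
    s = _scores_array(scores)
    return WeightVector(weights=1.0 / (s + PENALTY_OFFSET), scheme="inverse_penalty")


def proportional_weights(scores, normalize: bool = True) -> WeightVector:
    """Squared scores, normalized to mean 1 (ratios preserved).

    ``normalize=False`` returns the raw squared scores (0.9 → 0.81,
    0.3 → 0.09) before the mean-1 rescaling.
    """
    s = _scores_array(scores)
    raw = s**2
    m = raw.mean()
    if m <= 0:
        raise ValidationError("all scores are zero: proportional weights undefined")
    return WeightVector(weights=raw / m if normalize else raw, scheme="proportional_sq")


def apply_column_weights(X, w: WeightVector | np.ndarray) -> np.ndarray:
    """Multiply column ``j`` of ``X`` by ``w_j``."""
    Xm = as_2d(X, "X")
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if wv.size != Xm.shape[1]:
        raise ValidationError(f"{wv.size} weights for {Xm.shape[1]} columns")
    return Xm * wv[None, :]


def center_importance(kmap: KernelMap, scores) -> WeightVector:
    """Post-kernel importance of each center from its coordinates.

    A center close (coordinate-wise) to the origin along high-dCor features
    scores high; the 0.1 offset bounds the per-feature term at 10·dCor_j.
    """
    s = _scores_array(scores)
    C = np.asarray(kmap.centers, dtype=float)
    if s.size != C.shape[1]:
        raise ValidationError(f"{s.size} scores for centers with {C.shape[1]} features")
    imp = (s[None, :] / (np.abs(C) + IMPORTANCE_OFFSET)).sum(axis=1)
    return WeightVector(weights=imp, scheme="center_importance")


def hybrid_split(scores, n_direct: int, n_kernel: int) -> tuple[np.ndarray, np.ndarray]:
    """Ranks 1..n_direct kept raw; ranks n_direct+1..n_direct+n_kernel to the kernel.

    Ties broken by ascending column index.
    """
    s = _scores_array(scores)
    if n_direct < 0 or n_kernel < 0:
        raise ValidationError("split sizes must be nonnegative")
    if s.size < n_direct + n_kernel:
        raise ValidationError(
            f"need at least {n_direct + n_kernel} features, have {s.size}"
        )
    order = np.argsort(-s, kind="stable")
    return order[:n_direct].copy(), order[n_direct : n_direct + n_kernel].copy()
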