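"""The fifteen selection pipelines behind one fit/transform contract.

M1–M8 are the bespoke pipelines; M9–M15 wrap the classical filters.  Each
method is described by a :class:`MethodSpec` (stage hyperparameters) and
fitting returns a :class:`FittedSelector` that maps any same-width matrix
into the selected ``k_final``-dimensional representation using only state
estimated on the training fold.

"Selected features" live in the method's operating space: original columns
for M1/M2/M5 and the filter baselines, kernel centers for M3/M4/M6/M7, and
a mix of direct columns and centers for the hybrid M8.

Stage orders and hyperparameter defaults::

    M1  z-scored features → LASSO (5-fold CV, min-MSE λ) → top 14 |β|
    M2  LASSO pre-select 20 → degree-2 expansion (230 cols) → re-z-score
        → LASSO → top 14
    M3  RBF map (279 centers, median σ) → LASSO → top 14 centers
    M4  dCor all features → top 100 → × 1/(dCor+0.01) → RBF (279, median σ)
        → LASSO → top 14 centers
    M5  dCor → top 14 features directly
    M6  dCor top 50 → × dCor²/mean → RBF (200, 25th-pct σ)
        → elastic net α=0.9, 10-fold, 1-SE → top 14 centers
    M7  dCor top 30 → RBF (150, 30th-pct σ) → × center importance
        → elastic net α=0.85 → top 14 centers
    M8  dCor: top 7 direct + next 40 → RBF (100, 20th-pct σ)
        → [7 | 100] hybrid space → LASSO → top 14
    M9–M15  mRMR, ReliefF, ANOVA-F, χ², Fisher, MI, CFS → top 14 features

Counts assume the reference problem size (339 training rows, 279
features); on smaller data the center and pre-selection counts are clamped
to what the fold allows.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._validation import ValidationError, as_1d, as_2d
from .dcor import DCorScores, score_features
from .filters import cfs_select, mrmr_select, relieff_rank, univariate_scores
from .kernel import KernelConfig, KernelMap, fit_kernel_map, rbf_transform
from .sparse import SparseFit, fit_sparse_cv, top_k_by_coefficient
from .weighting import (
    WeightVector,
    apply_column_weights,
    center_importance,
    hybrid_split,
    inverse_penalty,
    proportional_weights,
)

__all__ = [
    "METHOD_IDS",
    "MethodSpec",
    "FittedSelector",
    "method_spec",
    "polynomial_expand",
    "fit_selector",
    "penalty_weighted_feature_selection",
]

BASELINE_FILTERS = {
    "M9": "mrmr",
    "M10": "relieff",
    "M11": "anova_f",
    "M12": "chi2",
    "M13": "fisher",
    "M14": "mutual_info",
    "M15": "cfs",
}
METHOD_IDS = tuple(f"M{i}" for i in range(1, 16))


@dataclass
class MethodSpec:
    method_id: str
    k_final: int = 14
    pre_select_n: Optional[int] = None
    n_centers: Optional[int] = None
    bandwidth_rule: str = "median"
    bandwidth_q: float = 50.0
    alpha: float = 1.0
    cv_folds: int = 5
    lambda_rule: str = "min_mse"
    n_direct: Optional[int] = None
    n_kernel: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.method_id not in METHOD_IDS:
            raise ValidationError(f"unknown method id {self.method_id!r}")
        if self.k_final < 1:
            raise ValidationError("k_final must be >= 1")

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


_DEFAULTS: dict[str, dict] = {
    "M1": dict(),
    "M2": dict(pre_select_n=20),
    "M3": dict(n_centers=279, bandwidth_rule="median"),
    "M4": dict(pre_select_n=100, n_centers=279, bandwidth_rule="median"),
    "M5": dict(),
    "M6": dict(pre_select_n=50, n_centers=200, bandwidth_rule="percentile",
               bandwidth_q=25.0, alpha=0.9, cv_folds=10, lambda_rule="one_se"),
    "M7": dict(pre_select_n=30, n_centers=150, bandwidth_rule="percentile",
               bandwidth_q=30.0, alpha=0.85),
    "M8": dict(n_direct=7, n_kernel=40, n_centers=100,
               bandwidth_rule="percentile", bandwidth_q=20.0),
}


def method_spec(method_id: str, k_final: int = 14, seed: int = 0, **overrides) -> MethodSpec:
    """A :class:`MethodSpec` populated with the method's default stage parameters."""
    kw = dict(_DEFAULTS.get(method_id, {}))
    kw.update(overrides)
    return MethodSpec(method_id=method_id, k_final=k_final, seed=seed, **kw)


def polynomial_expand(X) -> np.ndarray:
    """Degree-2 expansion: [originals | squares | pairwise interactions].

    ``d`` columns become ``2d + d(d−1)/2`` (20 → 230, 30 → 495, 40 → 860);
    interaction columns are ordered lexicographically by (i, j), i < j.
    """
    Xm = as_2d(X, "X")
    d = Xm.shape[1]
    blocks = [Xm, Xm**2]
    inter = [Xm[:, i] * Xm[:, j] for i in range(d) for j in range(i + 1, d)]
    if inter:
        blocks.append(np.column_stack(inter))
    return np.column_stack(blocks) if len(blocks) > 1 else blocks[0]


@dataclass
class FittedSelector:
    """Frozen transform state of one fitted pipeline."""

    method_id: str
    spec: MethodSpec
    selected: np.ndarray
    n_features_in: int
    # optional per-method state
    scores: Optional[DCorScores] = None
    pre_idx: Optional[np.ndarray] = None
    weights: Optional[WeightVector] = None
    kmap: Optional[KernelMap] = None
    direct_idx: Optional[np.ndarray] = None
    kernel_idx: Optional[np.ndarray] = None
    expand_mu: Optional[np.ndarray] = None
    expand_sd: Optional[np.ndarray] = None
    sparse_fit: Optional[SparseFit] = None

    def metadata(self) -> dict:
        md = {
            "method": self.method_id,
            "parameters": self.spec.as_dict(),
            "selected": [int(i) for i in self.selected],
        }
        if self.kmap is not None:
            md["sigma"] = float(self.kmap.sigma)
            md["sigma_source"] = "train sample-to-center distances, zeros excluded"
        return md

    def transform(self, X) -> np.ndarray:
        """Map samples into the selected ``k_final``-dimensional space."""
        Xm = as_2d(X, "X")
        if Xm.shape[1] != self.n_features_in:
            raise ValidationError(
                f"expected {self.n_features_in} columns, got {Xm.shape[1]}"
            )
        m = self.method_id
        if m in ("M1", "M5") or m in BASELINE_FILTERS:
            return Xm[:, self.selected]
        if m == "M2":
            E = polynomial_expand(Xm[:, self.pre_idx])
            E = (E - self.expand_mu) / self.expand_sd
            return E[:, self.selected]
        if m == "M3":
            return rbf_transform(Xm, self.kmap)[:, self.selected]
        if m in ("M4", "M6"):
            W = apply_column_weights(Xm[:, self.pre_idx], self.weights)
            return rbf_transform(W, self.kmap)[:, self.selected]
        if m == "M7":
            K = rbf_transform(Xm[:, self.pre_idx], self.kmap)
            return apply_column_weights(K, self.weights)[:, self.selected]
        if m == "M8":
            K = rbf_transform(Xm[:, self.kernel_idx], self.kmap)
            H = np.column_stack([Xm[:, self.direct_idx], K])
            return H[:, self.selected]
        raise ValidationError(f"unknown method {m!r}")  # pragma: no cover


@contextmanager
def _stage(method: str, name: str):
    try:
        yield
    except ValidationError as e:
        raise ValidationError(f"[{method}:{name}] {e}") from e


def _clamp_centers(n_centers: int, n_train: int) -> int:
    return min(n_centers, n_train)


def _lasso_top(X, y, spec: MethodSpec, k: int) -> tuple[np.ndarray, SparseFit]:
    fit = fit_sparse_cv(X, y, alpha=spec.alpha, cv_folds=spec.cv_folds,
                        rule=spec.lambda_rule, seed=spec.seed)
    return top_k_by_coefficient(fit, k), fit


def fit_selector(spec: MethodSpec, X_train, y_train) -> FittedSelector:
    """Run the method's stages in order on the training fold.

    ``X_train`` is expected already z-scored by the evaluation harness;
    ``y_train`` is the binary {0,1} label.
    """
    X = as_2d(X_train, "X_train")
    y = as_1d(y_train, "y_train")
    n, p = X.shape
    m = spec.method_id
    k = min(spec.k_final, p) if m in ("M1", "M5") or m in BASELINE_FILTERS else spec.k_final
    out = FittedSelector(method_id=m, spec=spec, selected=np.empty(0, int), n_features_in=p)

    if m in BASELINE_FILTERS:
        name = BASELINE_FILTERS[m]
        with _stage(m, name):
            if name == "mrmr":
                rk = mrmr_select(X, y, k=k)
            elif name == "relieff":
                rk = relieff_rank(X, y, seed=spec.seed)
            elif name == "cfs":
                rk = cfs_select(X, y)
            else:
                rk = univariate_scores(X, y, method=name)
        out.selected = rk.top_k(k)
        return out

    if m == "M1":
        with _stage(m, "lasso"):
            sel, fit = _lasso_top(X, y, spec, k)
        out.selected, out.sparse_fit = sel, fit
        return out

    if m == "M2":
        pre_n = min(spec.pre_select_n, p)
        with _stage(m, "pre_lasso"):
            pre, _ = _lasso_top(X, y, replace(spec, alpha=1.0, cv_folds=5,
                                              lambda_rule="min_mse"), pre_n)
        out.pre_idx = np.sort(pre)
        with _stage(m, "expand"):
            E = polynomial_expand(X[:, out.pre_idx])
        mu = E.mean(axis=0)
        sd = E.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        out.expand_mu, out.expand_sd = mu, sd
        En = (E - mu) / sd
        with _stage(m, "lasso"):
            out.selected, out.sparse_fit = _lasso_top(En, y, spec, min(spec.k_final, En.shape[1]))
        return out

    if m == "M3":
        cfg = KernelConfig(n_centers=_clamp_centers(spec.n_centers, n),
                           bandwidth_rule=spec.bandwidth_rule,
                           percentile_q=spec.bandwidth_q, seed=spec.seed)
        with _stage(m, "kernel"):
            out.kmap = fit_kernel_map(X, cfg)
            K = rbf_transform(X, out.kmap)
        with _stage(m, "lasso"):
            out.selected, out.sparse_fit = _lasso_top(K, y, spec, min(spec.k_final, K.shape[1]))
        return out

    # dCor-based methods share the scoring stage
    with _stage(m, "dcor"):
        scores = score_features(X, y)
    out.scores = scores

    if m == "M5":
        out.selected = scores.top_k(k)
        return out

    if m == "M4":
        pre = scores.top_k(min(spec.pre_select_n, p))
        out.pre_idx = np.sort(pre)
        with _stage(m, "penalty"):
            out.weights = inverse_penalty(scores.scores[out.pre_idx])
            W = apply_column_weights(X[:, out.pre_idx], out.weights)
        cfg = KernelConfig(n_centers=_clamp_centers(spec.n_centers, n),
                           bandwidth_rule=spec.bandwidth_rule,
                           percentile_q=spec.bandwidth_q, seed=spec.seed)
        with _stage(m, "kernel"):
            out.kmap = fit_kernel_map(W, cfg)
            K = rbf_transform(W, out.kmap)
        with _stage(m, "lasso"):
            out.selected, out.sparse_fit = _lasso_top(K, y, spec, min(spec.k_final, K.shape[1]))
        return out

    if m == "M6":
        pre = scores.top_k(min(spec.pre_select_n, p))
        out.pre_idx = np.sort(pre)
        with _stage(m, "weights"):
            out.weights = proportional_weights(scores.scores[out.pre_idx])
            W = apply_column_weights(X[:, out.pre_idx], out.weights)
        cfg = KernelConfig(n_centers=_clamp_centers(spec.n_centers, n),
                           bandwidth_rule=spec.bandwidth_rule,
                           percentile_q=spec.bandwidth_q, seed=spec.seed)
        with _stage(m, "kernel"):
            out.kmap = fit_kernel_map(W, cfg)
            K = rbf_transform(W, out.kmap)
        with _stage(m, "elastic_net"):
            out.selected, out.sparse_fit = _lasso_top(K, y, spec, min(spec.k_final, K.shape[1]))
        return out

    if m == "M7":
        pre = scores.top_k(min(spec.pre_select_n, p))
        out.pre_idx = np.sort(pre)
        cfg = KernelConfig(n_centers=_clamp_centers(spec.n_centers, n),
                           bandwidth_rule=spec.bandwidth_rule,
                           percentile_q=spec.bandwidth_q, seed=spec.seed)
        with _stage(m, "kernel"):
            out.kmap = fit_kernel_map(X[:, out.pre_idx], cfg)
            K = rbf_transform(X[:, out.pre_idx], out.kmap)
        with _stage(m, "post_weights"):
            out.weights = center_importance(out.kmap, scores.scores[out.pre_idx])
            Kw = apply_column_weights(K, out.weights)
        with _stage(m, "elastic_net"):
            out.selected, out.sparse_fit = _lasso_top(Kw, y, spec, min(spec.k_final, Kw.shape[1]))
        return out

    if m == "M8":
        n_direct = min(spec.n_direct, p)
        n_kernel = min(spec.n_kernel, p - n_direct)
        with _stage(m, "split"):
            direct, kern = hybrid_split(scores, n_direct, n_kernel)
        out.direct_idx, out.kernel_idx = direct, np.sort(kern)
        cfg = KernelConfig(n_centers=_clamp_centers(spec.n_centers, n),
                           bandwidth_rule=spec.bandwidth_rule,
                           percentile_q=spec.bandwidth_q, seed=spec.seed)
        with _stage(m, "kernel"):
            out.kmap = fit_kernel_map(X[:, out.kernel_idx], cfg)
            K = rbf_transform(X[:, out.kernel_idx], out.kmap)
        H = np.column_stack([X[:, out.direct_idx], K])
        with _stage(m, "lasso"):
            out.selected, out.sparse_fit = _lasso_top(H, y, spec, min(spec.k_final, H.shape[1]))
        return out

    raise ValidationError(f"unknown method {m!r}")  # pragma: no cover


def penalty_weighted_feature_selection(X, y, k: int, seed: int = 0) -> np.ndarray:
    """Inverse-penalty selection at the original-feature level.

    dCor → multiply columns by 1/(dCor+0.01) → LASSO → top-k |β| original
    features.  The feature-space analogue of the M4 cascade, used to study
    the redundancy-breaking effect of the penalty against greedy top-dCor
    selection (whose picks cluster inside correlated groups).
    """
    Xm = as_2d(X, "X")
    scores = score_features(Xm, y)
    W = apply_column_weights(Xm, inverse_penalty(scores))
    fit = fit_sparse_cv(W, y, alpha=1.0, cv_folds=5, rule="min_mse", seed=seed)
    return top_k_by_coefficient(fit, k)
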