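"""Cross-validated LASSO / elastic-net fitting and top-k coefficient extraction.

The selection stages regress the {0,1}-coded class label on a feature (or
kernel) matrix by penalized least squares

    min ||y - Xβ||² + λ [ α ||β||₁ + (1-α)/2 ||β||₂² ]

where ``α`` is the L1 fraction (α = 1 is the pure LASSO; the Index1SE-style
rule and the MinMSE rule pick λ from a cross-validated grid).  The
coordinate-descent solver is delegated to scikit-learn's ``enet_path``;
the λ grid, fold loop and selection rules live here.

Columns are expected to be standardized (or otherwise comparably scaled)
upstream; no internal standardization is performed.  An intercept is
handled by centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

from ._validation import ValidationError, as_1d, as_2d

__all__ = ["SparseFit", "fit_sparse_cv", "top_k_by_coefficient"]

N_LAMBDAS = 100
LAMBDA_RATIO = 1e-4  # λ_min / λ_max


@dataclass
class SparseFit:
    coefficients: np.ndarray
    lambda_grid: np.ndarray
    chosen_lambda: float
    rule: str
    alpha: float
    cv_folds: int
    seed: int
    cv_mse: np.ndarray | None = None
    cv_se: np.ndarray | None = None

    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def to_text(self, path, names=None) -> None:
        names = names if names is not None else [f"c{j}" for j in range(self.coefficients.size)]
        with open(path, "w") as fh:
            for name, b in zip(names, self.coefficients):
                fh.write(f"{name}\t{b:.12g}\n")


def _lambda_grid(Xc: np.ndarray, yc: np.ndarray, alpha: float) -> np.ndarray:
    n = Xc.shape[0]
    lam_max = np.max(np.abs(Xc.T @ yc)) / (n * alpha)
    if lam_max <= 0:
        raise ValidationError("design matrix carries no signal for the target")
    return np.geomspace(lam_max, lam_max * LAMBDA_RATIO, N_LAMBDAS)


def _path_coefs(Xc, yc, grid, alpha) -> np.ndarray:
    # kernel-feature columns are highly collinear; small-λ path steps may stop
    # at max_iter without closing the duality gap, which is harmless for the
    # coefficient ranking these fits feed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(Xc, yc, l1_ratio=alpha, alphas=grid, max_iter=2000)
    return coefs  # shape (p, n_lambdas)


def fit_sparse_cv(
    X,
    y,
    alpha: float = 1.0,
    cv_folds: int = 5,
    rule: str = "min_mse",
    seed: int = 0,
) -> SparseFit:
    """Fit an elastic-net path and choose λ by cross-validated MSE.

    ``rule="min_mse"`` picks the λ minimizing the mean CV MSE;
    ``rule="one_se"`` picks the largest λ whose mean CV MSE is within one
    standard error of the minimum (the more conservative choice).
    """
    Xm = as_2d(X, "X")
    yv = as_1d(y, "y")
    if Xm.shape[0] != yv.size:
        raise ValidationError("X and y disagree in row count")
    if not (0 < alpha <= 1):
        raise ValidationError("alpha (L1 fraction) must be in (0, 1]")
    if cv_folds < 2 or Xm.shape[0] <= cv_folds:
        raise ValidationError("need n > cv_folds >= 2")
    if rule not in ("min_mse", "one_se"):
        raise ValidationError(f"unknown lambda rule {rule!r}")
    if np.unique(yv).size < 2:
        raise ValidationError("degenerate target: only one distinct value")

    Xc = Xm - Xm.mean(axis=0)
    yc = yv - yv.mean()
    grid = _lambda_grid(Xc, yc, alpha)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((cv_folds, grid.size))
    for f, (tr, va) in enumerate(kf.split(Xm)):
        mu = Xm[tr].mean(axis=0)
        ym = yv[tr].mean()
        coefs = _path_coefs(Xm[tr] - mu, yv[tr] - ym, grid, alpha)
        pred = (Xm[va] - mu) @ coefs + ym  # (n_va, n_lambdas)
        fold_mse[f] = ((pred - yv[va][:, None]) ** 2).mean(axis=0)
    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)

    i_min = int(np.argmin(mean_mse))
    if rule == "min_mse":
        i_star = i_min
    else:
        # grid is descending, so the first index within one SE is the largest λ
        threshold = mean_mse[i_min] + se_mse[i_min]
        i_star = int(np.argmax(mean_mse <= threshold))

    coefs_full = _path_coefs(Xc, yc, grid, alpha)
    return SparseFit(
        coefficients=coefs_full[:, i_star].copy(),
        lambda_grid=grid,
        chosen_lambda=float(grid[i_star]),
        rule=rule,
        alpha=alpha,
        cv_folds=cv_folds,
        seed=seed,
        cv_mse=mean_mse,
        cv_se=se_mse,
    )


def top_k_by_coefficient(fit: SparseFit, k: int) -> np.ndarray:
    """Indices of the ``k`` largest |coefficients|, ties (and zeros) by index."""
    if k <= 0:
        raise ValidationError("k must be positive")
    beta = np.abs(fit.coefficients)
    if k > beta.size:
        raise ValidationError(f"k={k} exceeds {beta.size} columns")
    order = np.argsort(-beta, kind="stable")
    return order[:k]
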