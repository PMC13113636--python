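"""Classical filter selectors used as comparison baselines.

Seven methods: ANOVA-F, chi-square, Fisher score, mutual information (the
univariate scorers), ReliefF, mRMR (greedy MID variant) and CFS.  Each
returns a :class:`FilterRanking` whose ``ranking`` is a permutation of the
feature indices, best first.

Continuous features are discretized into 10 equal-frequency bins for the
chi-square, mutual-information and mRMR statistics.  ANOVA-F delegates to
scikit-learn's ``f_classif``; mutual information is the plug-in estimate on
the binned contingency table; ReliefF, mRMR and CFS are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import contingency
from sklearn.feature_selection import f_classif
from sklearn.metrics import mutual_info_score

from ._validation import ValidationError, as_1d, as_2d

__all__ = [
    "FilterRanking",
    "univariate_scores",
    "relieff_rank",
    "mrmr_select",
    "cfs_select",
    "discretize",
    "chi2_statistic",
]

N_BINS = 10


@dataclass
class FilterRanking:
    method: str
    scores: np.ndarray
    ranking: np.ndarray
    subset_size: int | None = None  # CFS/mRMR: the ranking's leading chosen subset

    def top_k(self, k: int) -> np.ndarray:
        if k <= 0 or k > self.ranking.size:
            raise ValidationError(f"k={k} out of range")
        return self.ranking[:k]


def _rank_desc(scores: np.ndarray) -> np.ndarray:
    # stable sort: ties broken by ascending index
    return np.argsort(-scores, kind="stable")


def discretize(x, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` integer codes."""
    v = as_1d(x, "x")
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, v, side="right")


def chi2_statistic(table) -> float:
    """Pearson χ² = Σ (O − E)² / E on a contingency table (no correction)."""
    O = np.asarray(table, dtype=float)
    O = O[O.sum(axis=1) > 0][:, O.sum(axis=0) > 0]
    if O.shape[0] < 2 or O.shape[1] < 2:
        return 0.0
    E = contingency.expected_freq(O)
    return float(((O - E) ** 2 / E).sum())


def _contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    bins = np.max(codes) + 1
    table = np.zeros((bins, 2))
    for b, c in zip(codes, y.astype(int)):
        table[b, c] += 1
    return table


def univariate_scores(X, y, method: str) -> FilterRanking:
    """Per-feature relevance scores for one of the univariate statistics.

    ``anova_f``: between/within class variance F ratio.
    ``fisher``: (μ₁ − μ₀)² / (s₁² + s₀²) with sample variances.
    ``chi2``: Pearson χ² on the 10-bin contingency table.
    ``mutual_info``: plug-in MI (nats) on the same binning.
    """
    Xm = as_2d(X, "X")
    yv = as_1d(y, "y").astype(int)
    if np.unique(yv).size != 2:
        raise ValidationError("binary target required")
    p = Xm.shape[1]
    scores = np.zeros(p)

    if method == "anova_f":
        with np.errstate(divide="ignore", invalid="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                F, _ = f_classif(Xm, yv)
        scores = np.where(np.isnan(F), 0.0, F)  # 0/0: no separation at all
    elif method == "fisher":
        m1, m0 = Xm[yv == 1], Xm[yv == 0]
        num = (m1.mean(axis=0) - m0.mean(axis=0)) ** 2
        den = m1.var(axis=0, ddof=1) + m0.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                              np.where(num > 0, np.inf, 0.0))
    elif method == "chi2":
        for j in range(p):
            scores[j] = chi2_statistic(_contingency(discretize(Xm[:, j]), yv))
    elif method == "mutual_info":
        for j in range(p):
            scores[j] = mutual_info_score(discretize(Xm[:, j]), yv)
    else:
        raise ValidationError(f"unknown univariate method {method!r}")
    return FilterRanking(method=method, scores=scores, ranking=_rank_desc(scores))


def relieff_rank(X, y, n_neighbors: int = 10, n_sample: int | None = None, seed: int = 0) -> FilterRanking:
    """Deterministic ReliefF weights for a binary target.

    Every instance (or a seeded sample of ``n_sample``) contributes: the
    feature weight rises with distance to the nearest misses and falls with
    distance to the nearest hits, differences range-normalized per feature.
    """
    Xm = as_2d(X, "X")
    yv = as_1d(y, "y").astype(int)
    n, p = Xm.shape
    span = Xm.max(axis=0) - Xm.min(axis=0)
    span[span == 0] = 1.0
    Xn = (Xm - Xm.min(axis=0)) / span

    if n_sample is None or n_sample >= n:
        sample = np.arange(n)
    else:
        sample = np.random.default_rng(seed).choice(n, size=n_sample, replace=False)

    w = np.zeros(p)
    m = sample.size
    for i in sample:
        diffs = np.abs(Xn - Xn[i])           # (n, p) range-normalized
        dist = diffs.sum(axis=1)             # Manhattan distance
        dist[i] = np.inf                     # exclude self
        for cls, sign in ((yv[i], -1.0), (1 - yv[i], +1.0)):
            mask = yv == cls
            mask_idx = np.flatnonzero(mask & (dist < np.inf))
            k = min(n_neighbors, mask_idx.size)
            if k < n_neighbors:
                warnings.warn(
                    f"class {cls} has only {mask_idx.size} usable neighbors; truncating",
                    stacklevel=2,
                )
            if k == 0:
                continue
            nn = mask_idx[np.argsort(dist[mask_idx], kind="stable")[:k]]
            w += sign * diffs[nn].sum(axis=0) / (m * k)
    return FilterRanking(method="relieff", scores=w, ranking=_rank_desc(w))


def _mi_matrixless(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    return float(mutual_info_score(codes_a, codes_b))


def mrmr_select(X, y, k: int) -> FilterRanking:
    """Greedy minimum-redundancy-maximum-relevance (MID difference variant).

    First pick maximizes I(X_j; y); each later pick maximizes
    I(X_j; y) − mean_{s selected} I(X_j; X_s).  MI on 10-bin codes.
    """
    Xm = as_2d(X, "X")
    yv = as_1d(y, "y").astype(int)
    p = Xm.shape[1]
    if k > p or k < 1:
        raise ValidationError(f"k={k} out of range for p={p}")
    codes = [discretize(Xm[:, j]) for j in range(p)]
    relevance = np.array([_mi_matrixless(c, yv) for c in codes])

    selected: list[int] = []
    redundancy = np.zeros(p)
    remaining = list(range(p))
    for step in range(k):
        if step == 0:
            obj = relevance.copy()
        else:
            obj = relevance - redundancy / step
        best = min(remaining, key=lambda j: (-obj[j], j))
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            redundancy[j] += _mi_matrixless(codes[j], codes[best])

    rest = sorted(remaining, key=lambda j: (-relevance[j], j))
    return FilterRanking(
        method="mrmr",
        scores=relevance,
        ranking=np.array(selected + rest, dtype=int),
        subset_size=k,
    )


def _merit(r_cf: np.ndarray, R_ff: np.ndarray, subset: list[int]) -> float:
    k = len(subset)
    rcf = np.abs(r_cf[subset]).mean()
    if k == 1:
        return rcf
    sub = R_ff[np.ix_(subset, subset)]
    rff = np.abs(sub[np.triu_indices(k, 1)]).mean()
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


def cfs_select(X, y) -> FilterRanking:
    """Correlation-based feature selection: forward greedy on the merit

    ``k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`` with Pearson correlations, stopping
    when no addition improves it.
    """
    Xm = as_2d(X, "X")
    yv = as_1d(y, "y")
    n, p = Xm.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(np.column_stack([Xm, yv]), rowvar=False)
    C = np.nan_to_num(C)
    r_cf = C[:p, p]
    R_ff = C[:p, :p]

    subset: list[int] = []
    best_merit = -np.inf
    remaining = list(range(p))
    while remaining:
        cands = [(_merit(r_cf, R_ff, subset + [j]), j) for j in remaining]
        merit, j = max(cands, key=lambda t: (t[0], -t[1]))
        if merit <= best_merit:
            break
        best_merit = merit
        subset.append(j)
        remaining.remove(j)

    rest = sorted(remaining, key=lambda j: (-abs(r_cf[j]), j))
    scores = np.abs(r_cf)
    return FilterRanking(method="cfs", scores=scores,
                         ranking=np.array(subset + rest, dtype=int),
                         subset_size=len(subset))
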