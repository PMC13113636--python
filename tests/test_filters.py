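"""Filter baselines against hand values and exhaustive / enumeration oracles."""

import numpy as np
import pytest

from dcorselect import cfs_select, mrmr_select, relieff_rank, univariate_scores
from dcorselect.filters import _merit, chi2_statistic, discretize


# ------------------------------------------------------------- univariate --

def test_no_separation_scores_zero(rng):
    x = rng.normal(size=40)
    X = np.column_stack([np.r_[x[:20], x[:20]]])  # identical in both classes
    y = np.r_[np.zeros(20), np.ones(20)]
    for method in ("anova_f", "fisher", "chi2", "mutual_info"):
        s = univariate_scores(X, y, method=method).scores
        assert s[0] == pytest.approx(0.0, abs=1e-12), method


def test_fisher_closed_form():
    """Exact sample stats: means 0 and 1, unit sample variances → 0.5."""
    n = 40
    c = np.sqrt((n - 1) / n)  # {±c} has sample variance exactly 1
    cls0 = np.r_[np.full(n // 2, -c), np.full(n // 2, c)]
    X = np.r_[cls0, 1.0 + cls0][:, None]
    y = np.r_[np.zeros(n), np.ones(n)]
    s = univariate_scores(X, y, method="fisher").scores
    assert s[0] == pytest.approx(0.5, abs=1e-12)


def test_chi2_hand_table():
    assert chi2_statistic([[20, 5], [5, 20]]) == pytest.approx(18.0)


def test_rankings_row_permutation_invariant(small_table, rng):
    X, y = small_table
    perm = rng.permutation(len(y))
    for method in ("anova_f", "fisher", "chi2", "mutual_info"):
        a = univariate_scores(X, y, method=method).ranking
        b = univariate_scores(X[perm], y[perm], method=method).ranking
        np.testing.assert_array_equal(a, b, err_msg=method)


def test_rankings_scale_invariant(small_table):
    X, y = small_table
    Xs = X.copy()
    Xs[:, 2] *= 37.0  # common positive rescaling of one feature
    for method in ("anova_f", "fisher"):
        a = univariate_scores(X, y, method=method).ranking
        b = univariate_scores(Xs, y, method=method).ranking
        np.testing.assert_array_equal(a, b, err_msg=method)


# ---------------------------------------------------------------- relieff --

def test_relieff_separating_beats_noise(rng):
    y = np.r_[np.zeros(30), np.ones(30)]
    sep = y + 0.05 * rng.normal(size=60)
    noise = rng.normal(size=60)
    r = relieff_rank(np.column_stack([sep, noise]), y)
    assert r.scores[0] > r.scores[1]
    assert r.ranking[0] == 0


def test_relieff_duplicate_columns_equal_weights(rng):
    y = rng.integers(0, 2, size=40)
    x = rng.normal(size=40) + y
    r = relieff_rank(np.column_stack([x, x, rng.normal(size=40)]), y)
    assert r.scores[0] == pytest.approx(r.scores[1], abs=1e-12)


def test_relieff_tiny_hand_oracle():
    """n=6, p=2, k=1 against an explicit nearest-neighbor enumeration."""
    X = np.array([[0.0, 0.1], [0.2, 0.9], [1.0, 0.3],
                  [0.9, 1.0], [0.15, 0.45], [0.7, 0.6]])
    y = np.array([0, 0, 0, 1, 1, 1])
    span = X.max(0) - X.min(0)
    Xn = (X - X.min(0)) / span
    w_oracle = np.zeros(2)
    for i in range(6):
        d = np.abs(Xn - Xn[i]).sum(axis=1)
        d[i] = np.inf
        hits = [j for j in range(6) if y[j] == y[i] and j != i]
        miss = [j for j in range(6) if y[j] != y[i]]
        h = min(hits, key=lambda j: d[j])
        m = min(miss, key=lambda j: d[j])
        w_oracle += (np.abs(Xn[m] - Xn[i]) - np.abs(Xn[h] - Xn[i])) / 6.0
    r = relieff_rank(X, y, n_neighbors=1)
    np.testing.assert_allclose(r.scores, w_oracle, atol=1e-12)


# ------------------------------------------------------------------- mrmr --

def _mi_plugin(a, b):
    """Independent plug-in MI (nats) from joint counts."""
    a, b = np.asarray(a), np.asarray(b)
    mi = 0.0
    n = a.size
    for va in np.unique(a):
        for vb in np.unique(b):
            pxy = np.mean((a == va) & (b == vb))
            if pxy > 0:
                mi += pxy * np.log(pxy / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def test_mrmr_redundancy_penalty(rng):
    y = rng.integers(0, 2, size=120)
    strong = y + 0.1 * rng.normal(size=120)
    complementary = 0.5 * y + rng.normal(size=120) * 0.8
    X = np.column_stack([strong, strong, complementary])
    r = mrmr_select(X, y, k=2)
    assert r.ranking[0] == 0        # most relevant first (tie with dup → low index)
    assert r.ranking[1] == 2        # redundancy pushes the duplicate down


def test_mrmr_k1_equals_top_mutual_info(small_table):
    X, y = small_table
    top_mi = univariate_scores(X, y, method="mutual_info").ranking[0]
    assert mrmr_select(X, y, k=1).ranking[0] == top_mi


def test_mrmr_matches_greedy_oracle(rng):
    X = rng.normal(size=(60, 4))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    codes = [discretize(X[:, j]) for j in range(4)]
    rel = np.array([_mi_plugin(c, y) for c in codes])
    selected, remaining = [], list(range(4))
    for step in range(4):
        if step == 0:
            obj = {j: rel[j] for j in remaining}
        else:
            obj = {j: rel[j] - np.mean([_mi_plugin(codes[j], codes[s]) for s in selected])
                   for j in remaining}
        best = min(remaining, key=lambda j: (-obj[j], j))
        selected.append(best)
        remaining.remove(best)
    r = mrmr_select(X, y, k=4)
    np.testing.assert_array_equal(r.ranking, selected)


# -------------------------------------------------------------------- cfs --

def test_cfs_single_relevant_feature(rng):
    y = rng.integers(0, 2, size=80).astype(float)
    X = np.column_stack([y + 0.2 * rng.normal(size=80),
                         rng.normal(size=80), rng.normal(size=80)])
    r = cfs_select(X, y)
    assert r.ranking[0] == 0
    assert r.subset_size >= 1


def test_cfs_duplicate_never_improves_merit(rng):
    y = rng.integers(0, 2, size=80).astype(float)
    x = y + 0.2 * rng.normal(size=80)
    X = np.column_stack([x, x + 1e-9 * rng.normal(size=80)])
    with np.errstate(all="ignore"):
        C = np.nan_to_num(np.corrcoef(np.column_stack([X, y]), rowvar=False))
    r_cf, R_ff = C[:2, 2], C[:2, :2]
    assert _merit(r_cf, R_ff, [0, 1]) <= _merit(r_cf, R_ff, [0]) + 1e-9


def test_cfs_matches_subset_enumeration(rng):
    """Greedy output equals the best-merit subset over all 7 subsets of 3 features."""
    y = rng.integers(0, 2, size=100).astype(float)
    X = np.column_stack([
        y + 0.3 * rng.normal(size=100),        # strong
        (1 - y) + 0.9 * rng.normal(size=100),  # moderate, complementary direction
        rng.normal(size=100),                  # noise
    ])
    with np.errstate(all="ignore"):
        C = np.nan_to_num(np.corrcoef(np.column_stack([X, y]), rowvar=False))
    r_cf, R_ff = C[:3, 3], C[:3, :3]
    subsets = [[0], [1], [2], [0, 1], [0, 2], [1, 2], [0, 1, 2]]
    best = max(subsets, key=lambda s: _merit(r_cf, R_ff, s))
    r = cfs_select(X, y)
    assert sorted(r.ranking[: r.subset_size].tolist()) == sorted(best)
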