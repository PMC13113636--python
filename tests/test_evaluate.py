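"""Evaluation harness: folds, normalization, classifier, metrics, paired tests."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata, t as t_dist

from dcorselect import (
    ClassifierSpec,
    ValidationError,
    apply_normalizer,
    compute_metrics,
    fit_normalizer,
    method_spec,
    paired_tests,
    run_comparison,
    stratified_kfold,
    sweep_k,
    train_classifier,
)
from dcorselect.simulate import SyntheticSpec, generate


# ------------------------------------------------------------------ folds --

def test_stratified_fold_sizes_reference():
    y = np.r_[np.zeros(245), np.ones(207)]  # 452 samples
    plan = stratified_kfold(y, n_folds=4, seed=0)
    sizes = np.bincount(plan.assignments)
    assert np.all(sizes == 113)


def test_stratified_exact_divisibility():
    y = np.r_[np.zeros(8), np.ones(4)]
    plan = stratified_kfold(y, n_folds=4, seed=1)
    for f in range(4):
        fold_y = y[plan.assignments == f]
        assert (fold_y == 0).sum() == 2 and (fold_y == 1).sum() == 1


def test_stratified_determinism_and_balance(rng):
    y = rng.integers(0, 2, size=101)
    a = stratified_kfold(y, 4, seed=9).assignments
    b = stratified_kfold(y, 4, seed=9).assignments
    np.testing.assert_array_equal(a, b)
    global_prop = y.mean()
    for f in range(4):
        fold_y = y[a == f]
        assert abs(fold_y.mean() - global_prop) <= 1.0 / fold_y.size + 1e-12
    with pytest.raises(ValidationError):
        stratified_kfold(np.r_[np.zeros(10), np.ones(2)], 4)


# ---------------------------------------------------------- normalization --

def test_normalizer_basic():
    norm = fit_normalizer(np.array([[2.0], [4.0]]))
    assert norm.mu[0] == 3.0
    out = apply_normalizer(norm, np.array([[2.0], [4.0]]))
    assert out.mean() == pytest.approx(0.0)


def test_normalizer_constant_column_and_nan():
    norm = fit_normalizer(np.full((5, 1), 7.0))
    assert norm.sd[0] == 1.0
    np.testing.assert_array_equal(apply_normalizer(norm, np.full((3, 1), 7.0)), 0.0)
    out = apply_normalizer(norm, np.array([[np.nan]]))
    assert out[0, 0] == 0.0


def test_no_leakage_train_statistics(rng):
    """Validation rows transformed with training μ, not their own."""
    Xtr = rng.normal(5.0, 1.0, size=(40, 3))
    Xva = rng.normal(-5.0, 1.0, size=(20, 3))
    norm = fit_normalizer(Xtr)
    out = apply_normalizer(norm, Xva)
    assert np.all(out.mean(axis=0) < -5)  # far from 0: no refit on validation
    refit = fit_normalizer(Xva)
    assert not np.allclose(norm.mu, refit.mu)


# ------------------------------------------------------------- classifier --

def test_classifier_learns_separable_blobs(rng):
    n = 100
    X = np.vstack([rng.normal(-2, 0.5, (n, 2)), rng.normal(2, 0.5, (n, 2))])
    y = np.r_[np.zeros(n), np.ones(n)].astype(int)
    model = train_classifier(ClassifierSpec(seed=0), X, y)
    p = model.predict_proba(X)
    assert ((p[:, 1] >= 0.5).astype(int) == y).mean() >= 0.95
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_classifier_deterministic(rng):
    X = rng.normal(size=(50, 3))
    y = rng.integers(0, 2, size=50)
    p1 = train_classifier(ClassifierSpec(seed=4), X, y).predict_proba(X)
    p2 = train_classifier(ClassifierSpec(seed=4), X, y).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


# ---------------------------------------------------------------- metrics --

def test_metrics_perfect_and_hand_case():
    m = compute_metrics([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
    assert all(v == 1.0 for v in m.as_dict().values())
    # TP=3 FP=1 FN=2 TN=4
    y = np.r_[np.ones(3), np.zeros(1), np.ones(2), np.zeros(4)]
    s = np.r_[np.full(3, 0.9), np.full(1, 0.9), np.full(2, 0.1), np.full(4, 0.1)]
    m = compute_metrics(y, s)
    assert m.precision == pytest.approx(0.75)
    assert m.recall == pytest.approx(0.6)
    assert m.specificity == pytest.approx(0.8)
    assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
    assert m.accuracy == pytest.approx(0.7)


def test_metrics_constant_scores_auc_half():
    m = compute_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
    assert m.roc_auc == 0.5


def test_metric_identities_random_confusions(rng):
    for _ in range(20):
        y = rng.integers(0, 2, size=30)
        s = rng.random(30)
        if y.min() == y.max():
            continue
        m = compute_metrics(y, s)
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))
        pred = (s >= 0.5).astype(int)
        assert m.accuracy == pytest.approx((pred == y).mean())
        assert 0 <= m.roc_auc <= 1


# ------------------------------------------------------------ paired tests --

def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumeration of all 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [np.sum(ranks[np.array(signs, bool)]) for signs in product([0, 1], repeat=n)]
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs + 1e-12).mean(), (ws >= w_obs - 1e-12).mean())
    return min(1.0, p)


def test_wilcoxon_floor_at_four_folds():
    r = paired_tests([0.8, 0.7, 0.9, 0.85], [0.7, 0.6, 0.8, 0.75])
    assert r.wilcoxon_p == pytest.approx(0.125)
    assert r.mean_diff == pytest.approx(0.1)


def test_equal_vectors_not_significant():
    r = paired_tests([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
    assert r.mean_diff == 0.0
    assert r.t_p == 1.0 and r.zero_variance
    assert not r.significant_t


def test_t_p_matches_closed_form(rng):
    a, b = rng.random(4), rng.random(4)
    d = a - b
    tstat = d.mean() / (d.std(ddof=1) / np.sqrt(4))
    p = 2 * t_dist.sf(abs(tstat), df=3)
    assert paired_tests(a, b).t_p == pytest.approx(p, abs=1e-10)


@pytest.mark.parametrize("n", range(3, 11))
def test_wilcoxon_matches_enumeration(n, rng):
    for _ in range(5):
        a = rng.random(n)
        b = rng.random(n)
        r = paired_tests(a, b)
        assert r.wilcoxon_p == pytest.approx(wilcoxon_exact_oracle(a - b), abs=1e-12)


# -------------------------------------------------------------- comparison --

@pytest.fixture(scope="module")
def tiny_data():
    X, y, _ = generate(SyntheticSpec(n=120, n_noise=10, seed=8))
    return X.to_numpy(), y


def test_run_comparison_shape_and_determinism(tiny_data):
    X, y = tiny_data
    specs = [method_spec("M5", k_final=5), method_spec("M11", k_final=5)]
    rep1 = run_comparison(specs, X, y, n_folds=4, seed=3, reference="M5")
    rep2 = run_comparison(specs, X, y, n_folds=4, seed=3, reference="M5")
    assert len(rep1.per_fold) == 2 * 4
    assert (rep1.per_fold["error"] == "").all()
    np.testing.assert_array_equal(rep1.per_fold["accuracy"].to_numpy(),
                                  rep2.per_fold["accuracy"].to_numpy())
    assert set(rep1.tests["method"]) == {"M11"}


def test_nonmonotonic_signals_favor_dcor_over_lasso():
    """Variance-coded (quadratic) signals: top-dCor beats plain-LASSO selection."""
    wins = 0
    for seed in range(10):
        X, y, _ = generate(SyntheticSpec(
            n=240, n_linear=0, n_quadratic=4, n_sinusoidal=0,
            n_clusters=0, n_noise=40, effect=1.5, seed=seed))
        rep = run_comparison(
            [method_spec("M1", k_final=4), method_spec("M5", k_final=4)],
            X.to_numpy(), y, n_folds=4, seed=seed, reference="M5")
        s = rep.summary.set_index("method")["mean_accuracy"]
        wins += int(s["M5"] > s["M1"])
    assert wins >= 6


def test_sweep_k_runs_and_records_spread(tiny_data):
    X, y = tiny_data
    df = sweep_k(method_spec("M5"), X, y, ks=(3, 5), n_folds=3, seed=2)
    assert list(df["k"]) == [3, 5]
    assert np.isfinite(df.attrs["spread"])
    assert df["mean_accuracy"].between(0, 1).all()
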