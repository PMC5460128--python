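import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from peristroma.classify import (
    EAConfig,
    auc_score,
    bootstrap_auc_ci,
    ea_feature_pool,
    fit_logistic,
    loocv_evaluate,
    predict_logistic,
    roc_points,
    univariate_screen,
    youden_threshold,
)

from _oracles import brute_auc, brute_youden


# ---------------------------------------------------------------------------
# AUC and Youden primitives


def test_auc_known_example():
    assert auc_score([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)


def test_auc_matches_pairwise_concordance():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(6, 60))
        y = rng.integers(0, 2, size=n)
        if y.all() or not y.any():
            continue
        s = np.round(rng.normal(size=n), 1)  # coarse scores force ties
        assert auc_score(y, s) == pytest.approx(brute_auc(y, s), abs=1e-12)


def test_auc_equals_trapezoidal_roc_area():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=50)
    y[:2] = [0, 1]
    s = np.round(rng.random(50), 2)
    pts = roc_points(y, s).sort_values("fpr")
    area = float(np.trapezoid(pts.tpr, pts.fpr))
    assert auc_score(y, s) == pytest.approx(area, abs=1e-12)


def test_youden_perfect_separation():
    t, sens, spec = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert sens == 1.0 and spec == 1.0


def test_youden_no_discrimination():
    t, sens, spec = youden_threshold([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
    assert sens + spec - 1 == pytest.approx(0.0)


def test_youden_known_example_lowest_threshold_on_tie():
    t, sens, spec = youden_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert sens + spec - 1 == pytest.approx(0.5)
    assert t == pytest.approx(0.225)  # J ties at 0.225 and 0.6; lowest wins
    assert (sens, spec) == (1.0, 0.5)


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(6, 40))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        s = np.round(rng.random(n), 1)
        ours = youden_threshold(s, y)
        oracle = brute_youden(s, y)
        assert ours == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# logistic fit


def test_logistic_matches_sklearn():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    y = (X @ [1.0, -0.5, 0.2, 0.0] + rng.normal(size=60) > 0).astype(int)
    ridge = 1e-4
    beta = fit_logistic(X, y, ridge=ridge)
    sk = LogisticRegression(C=1.0 / ridge, tol=1e-10, max_iter=10_000)
    sk.fit(X, y)
    np.testing.assert_allclose(beta[0], sk.intercept_[0], atol=1e-4)
    np.testing.assert_allclose(beta[1:], sk.coef_[0], atol=1e-4)


def test_logistic_finite_under_perfect_separation():
    X = np.r_[np.full((10, 1), -1.0), np.full((10, 1), 1.0)]
    y = np.r_[np.zeros(10), np.ones(10)]
    beta = fit_logistic(X, y, ridge=1e-4)
    assert np.isfinite(beta).all()
    p = predict_logistic(beta, X)
    assert auc_score(y, p) == 1.0


# ---------------------------------------------------------------------------
# univariate screening


def test_univariate_perfect_feature():
    y = np.r_[np.zeros(10), np.ones(10)].astype(int)
    X = np.c_[y.astype(float), np.random.default_rng(4).normal(size=20)]
    res = univariate_screen(X, y, ["label_copy", "noise"], n_boot=200)
    top = res.iloc[0]
    assert top.feature == "label_copy"
    assert top.auc == 1.0 and top.sensitivity == 1.0 and top.specificity == 1.0
    assert top.separable


def test_univariate_null_feature_near_chance():
    rng = np.random.default_rng(5)
    n1 = n0 = 40
    y = np.r_[np.zeros(n0), np.ones(n1)].astype(int)
    X = rng.normal(size=(80, 1))
    res = univariate_screen(X, y, ["noise"], n_boot=200)
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # Mann-Whitney null SE
    assert abs(res.iloc[0].auc - 0.5) < 3 * se


def test_bootstrap_ci_brackets_auc():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, size=60)
    y[:2] = [0, 1]
    s = rng.random(60) + 0.5 * y
    lo, hi = bootstrap_auc_ci(y, s, n_boot=500, seed=1)
    assert 0 <= lo <= auc_score(y, s) <= hi <= 1


# ---------------------------------------------------------------------------
# evolutionary search


def _onemax(chrom):
    return chrom.sum() / chrom.size


def test_ea_elitism_makes_best_fitness_nondecreasing():
    cfg = EAConfig(population_size=20, max_generations=40, seed=1)
    res = ea_feature_pool(np.zeros((4, 12)), np.array([0, 0, 1, 1]), cfg,
                          fitness_fn=_onemax)
    assert all(b >= a for a, b in zip(res.history, res.history[1:]))


def test_ea_deterministic_given_seed():
    cfg = EAConfig(population_size=20, max_generations=20, seed=9)
    runs = [
        ea_feature_pool(np.zeros((4, 15)), np.array([0, 0, 1, 1]), cfg,
                        fitness_fn=_onemax)
        for _ in range(2)
    ]
    np.testing.assert_array_equal(runs[0].mask, runs[1].mask)
    assert runs[0].history == runs[1].history


def test_ea_single_informative_feature_selected():
    rng = np.random.default_rng(7)
    y = np.r_[np.zeros(15), np.ones(15)].astype(int)
    X = (y + rng.normal(0, 0.3, size=30)).reshape(-1, 1)
    cfg = EAConfig(population_size=10, max_generations=10, seed=2)
    res = ea_feature_pool(X, y, cfg)
    assert res.mask.tolist() == [True]
    assert res.best_fitness > 0.9


def test_ea_config_validation():
    with pytest.raises(ValueError):
        EAConfig(population_size=11)
    with pytest.raises(ValueError):
        EAConfig(mutation_prob=1.5)


# ---------------------------------------------------------------------------
# LOOCV wrapper evaluation


def test_loocv_perfect_pool_feature():
    rng = np.random.default_rng(8)
    y = np.r_[np.zeros(10), np.ones(10)].astype(int)
    X = np.c_[y + rng.normal(0, 0.05, 20), rng.normal(size=(20, 3))]
    report = loocv_evaluate(X, y, ["good", "n1", "n2", "n3"],
                            np.ones(4, bool), n_boot=200, seed=0)
    assert report.auc == 1.0
    assert report.sensitivity == 1.0 and report.specificity == 1.0
    assert report.selection_frequency["good"] == 1.0


def test_loocv_selection_frequency_bookkeeping():
    rng = np.random.default_rng(9)
    y = np.r_[np.zeros(8), np.ones(8)].astype(int)
    X = rng.normal(size=(16, 5))
    report = loocv_evaluate(X, y, list("abcde"), np.ones(5, bool),
                            n_boot=100, seed=0)
    mean_size = np.mean([len(s) for s in report.selected_per_fold])
    assert report.selection_frequency.sum() == pytest.approx(mean_size)


def test_loocv_preconditions():
    with pytest.raises(ValueError):
        loocv_evaluate(np.zeros((6, 2)), np.array([0, 0, 0, 1, 1, 1]),
                       ["a", "b"], np.ones(2, bool))


def test_loocv_handles_missing_values():
    rng = np.random.default_rng(10)
    y = np.r_[np.zeros(10), np.ones(10)].astype(int)
    X = np.c_[y + rng.normal(0, 0.1, 20), rng.normal(size=(20, 2))]
    X[::3, 1] = np.nan
    X[:, 2] = np.nan  # entirely missing column
    report = loocv_evaluate(X, y, ["good", "patchy", "void"],
                            np.ones(3, bool), n_boot=100, seed=0)
    assert np.isfinite(report.scores).all()
    assert report.auc > 0.9
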