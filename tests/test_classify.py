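"""Feature selection, SVM tuning, and the iterative classification loop."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from stressdyn.classify import (
    ClassifierConfig,
    _fit_and_score,
    auc_mann_whitney,
    correlation_filter,
    ks_select,
    run_iterations,
    stability_report,
    tune_svm,
)

FAST = ClassifierConfig(cv_folds=3, cv_repeats=1, c_grid=(1.0, 10.0),
                        gamma_grid=(0.1, 1.0))


def _labels(n_pos, n_neg):
    return pd.Series(["severe"] * n_pos + ["non_severe"] * n_neg)


def _separable_matrix(n=40, p=6, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    y = _labels(n // 2, n - n // 2)
    x[: n // 2, 0] += shift  # one informative feature
    x[: n // 2, 1] += shift
    df = pd.DataFrame(x, index=[f"c{i}" for i in range(n)],
                      columns=[f"f{j}" for j in range(p)])
    y.index = df.index
    return df, y


def test_ks_select_worked_example():
    x = pd.DataFrame({
        "sep": [1, 2, 3, 4, 5, 10, 11, 12, 13, 14],
        "flat": [7.0] * 10,
    })
    y = _labels(5, 5)
    y.index = x.index
    p = ks_select(x, y)
    # disjoint samples: D = 1, exact p = 2 / C(10,5)
    assert p["sep"] == pytest.approx(2 / 252)
    assert p["flat"] == 1.0
    kept = p[p < 0.05]
    assert list(kept.index) == ["sep"]


def test_ks_select_null_retention_rate():
    """Features independent of the labels survive the KS gate at roughly the
    alpha rate."""
    rng = np.random.default_rng(3)
    rates = []
    y = _labels(20, 20)
    for _ in range(200):
        x = pd.DataFrame(rng.normal(size=(40, 10)))
        y.index = x.index
        p = ks_select(x, y)
        rates.append(np.mean(p.to_numpy() < 0.05))
    # KS p-values are discrete/conservative at n=20+20: retention <= alpha
    assert 0.0 < np.mean(rates) < 0.07


def test_correlation_filter_drops_duplicates():
    rng = np.random.default_rng(0)
    f1 = rng.normal(size=50)
    x = pd.DataFrame({"f1": f1, "f2": 2.0 * f1, "f3": rng.normal(size=50)})
    kept = correlation_filter(x, ["f1", "f2", "f3"], threshold=0.8)
    assert kept == ["f1", "f3"]


def test_correlation_filter_boundary_is_strict():
    rng = np.random.default_rng(1)
    a = rng.normal(size=2000)
    noise = rng.normal(size=2000)
    # construct b with correlation very close to 0.8, slightly below
    b = 0.8 * a + np.sqrt(1 - 0.8**2) * noise
    r = np.corrcoef(a, b)[0, 1]
    x = pd.DataFrame({"a": a, "b": b})
    kept = correlation_filter(x, ["a", "b"], threshold=abs(r))  # |r| == threshold
    assert kept == ["a", "b"]  # strictly-greater rule keeps the boundary case


def test_auc_equals_mann_whitney():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=30)
    labels = np.array(["severe"] * 12 + ["non_severe"] * 18)
    sk = roc_auc_score((labels == "severe").astype(int), scores)
    assert auc_mann_whitney(scores, labels) == pytest.approx(sk)


def test_tune_svm_separable_reaches_perfect_cv_auc():
    x, y = _separable_matrix(n=30, shift=6.0)
    tuned = tune_svm(x, y, FAST, rng_seed=0)
    assert tuned["cv_auc"] == pytest.approx(1.0)


def test_tune_svm_permuted_labels_chance_level():
    x, y = _separable_matrix(n=40, shift=0.0, seed=5)  # no signal at all
    tuned = tune_svm(x, y, ClassifierConfig(cv_folds=5, cv_repeats=3,
                                            c_grid=(1.0,), gamma_grid=(0.1,)),
                     rng_seed=1)
    assert 0.3 < tuned["cv_auc"] < 0.7


def test_tune_svm_tie_breaks_to_least_complex():
    x, y = _separable_matrix(n=30, shift=8.0)
    cfg = ClassifierConfig(cv_folds=3, cv_repeats=1, c_grid=(0.1, 1.0, 10.0),
                           gamma_grid=(0.01, 0.1))
    tuned = tune_svm(x, y, cfg, rng_seed=0)
    # strongly separable: many settings reach the max; smallest C/gamma wins
    grid_best = (tuned["C"], tuned["gamma"])
    assert grid_best[0] <= 1.0


def test_no_leakage_from_test_labels():
    """Shuffling the held-out labels cannot change feature selection or the
    tuned model (selection and tuning see training data only)."""
    x, y = _separable_matrix(n=40, shift=3.0, seed=7)
    train_idx, test_idx = x.index[:32], x.index[32:]
    run1 = _fit_and_score(x, y, train_idx, test_idx, FAST, rng_seed=0)
    y_shuffled = y.copy()
    rng = np.random.default_rng(0)
    y_shuffled.loc[test_idx] = rng.permutation(y.loc[test_idx].to_numpy())
    run2 = _fit_and_score(x, y_shuffled, train_idx, test_idx, FAST, rng_seed=0)
    assert run1.selected_features == run2.selected_features
    assert run1.tuned == run2.tuned
    np.testing.assert_allclose(run1.test_scores, run2.test_scores)


def test_run_iterations_deterministic_and_stratified():
    x, y = _separable_matrix(n=40, shift=3.0, seed=9)
    runs1, s1 = run_iterations(x, y, n_iter=4, rng_seed=11, config=FAST)
    runs2, s2 = run_iterations(x, y, n_iter=4, rng_seed=11, config=FAST)
    assert s1 == s2
    for r1, r2 in zip(runs1, runs2):
        assert r1.selected_features == r2.selected_features
        assert r1.test_index == r2.test_index
        np.testing.assert_allclose(r1.test_scores, r2.test_scores)
        # stratified 80/20: disjoint, both classes in the test set
        assert not set(r1.train_index) & set(r1.test_index)
        assert len(np.unique(r1.test_labels)) == 2
    with pytest.raises(ValueError):
        run_iterations(x, y, n_iter=0)


def test_separable_iterations_reach_high_auc():
    x, y = _separable_matrix(n=40, shift=5.0, seed=13)
    _, summary = run_iterations(x, y, n_iter=6, rng_seed=2, config=FAST)
    assert summary["mean_roc_auc"] >= 0.95
    assert summary["mean_sensitivity"] > 0.8
    assert summary["mean_specificity"] > 0.8


def test_stability_report_rules():
    x, y = _separable_matrix(n=40, shift=5.0, seed=13)
    runs, _ = run_iterations(x, y, n_iter=8, rng_seed=2, config=FAST)
    report = stability_report(runs, x.columns, x.index)
    assert report.selection_counts.between(0, 8).all()
    # one planted informative feature dominates selection; its shifted twin
    # is redundant (r > 0.8 with f0) and is removed by the correlation filter
    assert report.selection_counts["f0"] == 8
    assert report.selection_counts["f1"] == 0
    # boundary: stable requires strictly more than 75% of iterations
    fake = runs[:1]
    rep1 = stability_report(fake, x.columns, x.index)
    # a feature selected in the single run has count 1 > 0.75 -> stable
    assert set(rep1.stable_features) == set(runs[0].selected_features)
    # compounds never tested have NaN correct fraction
    never = report.compound_correct_fraction.isna()
    tested = set()
    for r in runs:
        tested |= set(r.test_index)
    assert set(report.compound_correct_fraction.index[never]) == set(x.index) - tested
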