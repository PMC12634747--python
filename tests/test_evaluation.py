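"""ROC machinery: AUC estimators, bootstrap, jackknife, cumulative ROC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maskscope.errors import ParameterError
from maskscope.evaluation import (
    auc_mann_whitney,
    bootstrap_auc_ci,
    ci_to_se,
    compare_proportions,
    cumulative_roc,
    independent_auc_ztest,
    paired_auc_test,
    roc_curve_points,
)


def brute_force_auc(scores, labels):
    """Exhaustive pair-count oracle with 0.5 tie credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def trapezoid_auc(scores, labels):
    curve = roc_curve_points(scores, labels)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


class TestAucMannWhitney:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 3], [0, 0, 1]) == 1.0

    def test_pure_ties_give_half(self):
        assert auc_mann_whitney([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_and_trapezoid(self, rng):
        for _ in range(25):
            n = 30
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            a = auc_mann_whitney(scores, labels)
            assert a == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert a == pytest.approx(trapezoid_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_label_flip_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            1.0 - auc_mann_whitney(scores, 1 - labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            auc_mann_whitney([1, 2], [1, 1])


class TestBootstrapCi:
    def test_seed_reproducibility(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        b = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        assert a == b

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(10):
            scores = rng.normal(size=120)
            labels = (scores + rng.normal(size=120) > 0).astype(int)
            auc = auc_mann_whitney(scores, labels)
            lo, hi = bootstrap_auc_ci(scores, labels, B=400, seed=3)
            assert lo <= auc <= hi

    def test_small_b_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_auc_ci([1, 2], [0, 1], B=10)


class TestPairedAucTest:
    def test_identical_predictors(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        auc_a, auc_b, diff, se, p = paired_auc_test(scores, scores, labels)
        assert diff == 0.0 and p == 1.0

    def test_jackknife_se_close_to_bootstrap_se(self, rng):
        """Jackknife and bootstrap SEs of the AUC difference agree ~20%."""
        n = 200
        x = np.r_[rng.normal(0.8, 1, n), rng.normal(0, 1, n)]
        labels = np.r_[np.ones(n, int), np.zeros(n, int)]
        y = x + rng.normal(0, 1.2, 2 * n)
        *_, se_jk, _ = paired_auc_test(x, y, labels)
        diffs = []
        for _ in range(400):
            idx = rng.integers(0, 2 * n, 2 * n)
            if labels[idx].min() == labels[idx].max():
                continue
            diffs.append(
                auc_mann_whitney(x[idx], labels[idx])
                - auc_mann_whitney(y[idx], labels[idx])
            )
        se_boot = np.std(diffs, ddof=1)
        assert se_jk == pytest.approx(se_boot, rel=0.2)

    def test_strong_difference_detected(self, rng):
        hits = 0
        for _ in range(20):
            n = 200
            labels = np.r_[np.ones(n, int), np.zeros(n, int)]
            strong = np.r_[rng.normal(1.8, 1, n), rng.normal(0, 1, n)]
            weak = np.r_[rng.normal(0.35, 1, n), rng.normal(0, 1, n)]
            *_, p = paired_auc_test(strong, weak, labels)
            hits += p < 0.05
        assert hits >= 19

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            paired_auc_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestIndependentZtest:
    def test_equal_aucs(self):
        z, p = independent_auc_ztest(0.7, 0.02, 0.7, 0.05)
        assert z == 0.0 and p == 1.0

    def test_published_comparison_order_of_magnitude(self):
        """0.69 (0.66-0.73) vs 0.75 (0.68-0.82): z ~ -1.5, p ~ 0.13."""
        z, p = independent_auc_ztest(
            0.69, ci_to_se(0.66, 0.73), 0.75, ci_to_se(0.68, 0.82)
        )
        assert z == pytest.approx(-1.5, abs=0.2)
        assert p == pytest.approx(0.13, abs=0.04)

    def test_vanishing_se_forces_rejection(self):
        _, p = independent_auc_ztest(0.7, 1e-12, 0.75, 1e-12)
        assert p < 1e-6


class TestCumulativeRoc:
    def test_perfectly_ordered_categories(self):
        scores = np.r_[np.zeros(5), np.ones(5), 2 * np.ones(5)]
        cats = np.r_[np.ones(5), 3 * np.ones(5), 4 * np.ones(5)].astype(int)
        res = cumulative_roc(scores, cats, B=200, seed=1)
        assert res.auc_low_vs_rest == 1.0
        assert res.auc_rest_vs_high == 1.0
        assert res.counts == {"1": 5, "3": 5, "4": 5}

    def test_empty_intermediate_collapses_to_binary(self, rng):
        scores = rng.normal(size=40)
        cats = np.r_[np.ones(20, int), 4 * np.ones(20, int)]
        res = cumulative_roc(scores, cats, B=200, seed=2)
        binary = auc_mann_whitney(scores, (cats == 4).astype(int))
        assert res.auc_low_vs_rest == pytest.approx(binary, abs=1e-12)
        assert res.auc_rest_vs_high == pytest.approx(binary, abs=1e-12)

    def test_matches_brute_force_on_each_split(self, rng):
        scores = np.round(rng.normal(size=30), 1)
        cats = rng.choice([1, 3, 4], size=30)
        while len(np.unique(cats)) < 3:
            cats = rng.choice([1, 3, 4], size=30)
        res = cumulative_roc(scores, cats, B=200, seed=3)
        assert res.auc_low_vs_rest == pytest.approx(
            brute_force_auc(scores, (cats != 1).astype(int)), abs=1e-12
        )
        assert res.auc_rest_vs_high == pytest.approx(
            brute_force_auc(scores, (cats == 4).astype(int)), abs=1e-12
        )

    def test_single_category_rejected(self):
        with pytest.raises(ParameterError):
            cumulative_roc([1, 2, 3], [1, 1, 1])


class TestCompareProportions:
    def test_published_visibility_counts(self):
        p1, p2, chi2, p = compare_proportions(629, 768, 228, 411)
        assert (p1, p2) == (82, 55)
        assert p < 0.001

    def test_equal_proportions(self):
        _, _, _, p = compare_proportions(50, 100, 50, 100)
        assert p == pytest.approx(1.0)

    def test_close_to_fisher_exact(self):
        from scipy import stats

        k1, n1, k2, n2 = 80, 200, 60, 200
        *_, p_chi = compare_proportions(k1, n1, k2, n2)
        _, p_fisher = stats.fisher_exact(
            [[k1, n1 - k1], [k2, n2 - k2]]
        )
        assert abs(p_chi - p_fisher) < 0.02

    def test_zero_margin_falls_back_to_fisher(self):
        p1, p2, chi2, p = compare_proportions(0, 10, 0, 12)
        assert np.isnan(chi2) and p == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            compare_proportions(5, 3, 1, 2)
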