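from fractions import Fraction

import numpy as np
import pytest

from esis import (
    SurvivalSamples,
    dichotomize,
    fit_penalized_ph,
    generate,
    logrank_test,
    naive_variance_screen,
    run_workflow,
    stratified_split,
)

from conftest import random_survival


class TestStratifiedSplit:
    def test_four_to_one_balanced_strata(self):
        y = np.arange(1.0, 21.0)
        delta = np.array([1] * 10 + [0] * 10)
        s = SurvivalSamples(y, delta)
        train, test = stratified_split(s, ratio=(4, 1), seed=0)
        assert train.size == 16 and test.size == 4
        assert delta[train].sum() == 8 and delta[test].sum() == 2

    def test_cohort_sized_split(self, rng):
        # 473 samples with 207 events at 4:1 -> 379 train / 94 test
        delta = np.zeros(473, dtype=int)
        delta[rng.choice(473, 207, replace=False)] = 1
        s = SurvivalSamples(rng.exponential(10, 473) + 0.1, delta)
        train, test = stratified_split(s, ratio=(4, 1), seed=3)
        assert train.size == 379 and test.size == 94

    def test_seed_determinism_and_disjointness(self, rng):
        s = random_survival(rng, 50)
        a = stratified_split(s, seed=9)
        b = stratified_split(s, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        assert set(a[0]) | set(a[1]) == set(range(50))
        assert not set(a[0]) & set(a[1])

    def test_tiny_stratum_rejected(self):
        s = SurvivalSamples([1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.raises(ValueError):
            stratified_split(s)


class TestDichotomize:
    def test_all_below_cutoff(self):
        assert dichotomize([1.0, 2.0, 3.0], 5.0).tolist() == ["low"] * 3

    def test_median_cutoff_balances_groups(self, rng):
        for n in (20, 21):
            scores = rng.standard_normal(n)
            groups = dichotomize(scores, float(np.median(scores)))
            high = int((groups == "high").sum())
            assert abs(high - (n - high)) <= 1

    def test_external_cohort_uses_training_cutoff_unchanged(self, rng):
        train = rng.standard_normal(30)
        cutoff = float(np.median(train))
        external = rng.standard_normal(15) + 2.0  # shifted: groups need not balance
        groups = dichotomize(external, cutoff)
        assert (groups == "high").sum() > (groups == "low").sum()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        y = np.array([2.0, 4.0, 6.0, 8.0] * 2)
        delta = np.array([1, 0, 1, 1] * 2)
        groups = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank_test(SurvivalSamples(y, delta), groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # interleaved event times 1..8, no censoring; O-E = 2 - (3/7+2/5+1/3)
        # and V = 1 + 12/49 + 6/25 + 2/9, so chi2 = (88/105)^2 / (18821/11025)
        y = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0])
        groups = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank_test(SurvivalSamples(y, np.ones(8, dtype=int)), groups)
        expected = float(Fraction(88, 105) ** 2 / (Fraction(18821, 11025)))
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert 0 < p < 1

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(50):
            n = int(rng.integers(15, 60))
            s = random_survival(rng, n)
            g = rng.integers(0, 2, n)
            if len(np.unique(g)) < 2:
                g[0] = 1 - g[0]
            chi2, p = logrank_test(s, g)
            ref = ll_logrank(s.y[g == 0], s.y[g == 1], s.delta[g == 0], s.delta[g == 1])
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_requires_two_groups_and_events(self, rng):
        s = random_survival(rng, 10)
        with pytest.raises(ValueError):
            logrank_test(s, ["a"] * 10)
        s2 = SurvivalSamples([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            logrank_test(s2, ["a", "b"])


class TestPenalizedPH:
    def test_recovers_single_strong_gene(self):
        rng = np.random.default_rng(21)
        n = 150
        X = rng.standard_normal((n, 5))
        t = rng.exponential(1.0, n) / np.exp(1.5 * X[:, 2])
        s = SurvivalSamples(t + 1e-6, np.ones(n, dtype=int))
        coefs, scores, alpha = fit_penalized_ph(X, s, cv_folds=5, seed=0)
        assert coefs[2] > 0
        assert abs(coefs[2]) == pytest.approx(np.max(np.abs(coefs)))
        np.testing.assert_allclose(scores, X @ coefs)

    def test_heavy_penalty_zeroes_noise(self, rng):
        s = random_survival(rng, 60)
        X = rng.standard_normal((60, 8))
        coefs, scores, _ = fit_penalized_ph(X, s, alpha=10.0)
        assert np.all(coefs == 0.0)
        assert np.ptp(scores) == 0.0

    def test_deterministic_given_seed(self, rng):
        s = random_survival(rng, 80)
        X = rng.standard_normal((80, 6))
        a = fit_penalized_ph(X, s, cv_folds=5, seed=4)
        b = fit_penalized_ph(X, s, cv_folds=5, seed=4)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]


class TestNaiveVarianceScreen:
    def test_example(self):
        X = np.array([[0.0, 0.0, 0.0], [3.0, 1.0, 2.0], [-3.0, -1.0, -2.0]])
        assert naive_variance_screen(X, 2).tolist() == [0, 2]

    def test_top_k_equals_p(self, rng):
        X = rng.standard_normal((10, 4))
        assert naive_variance_screen(X, 4).tolist() == [0, 1, 2, 3]

    def test_sort_oracle(self, rng):
        X = rng.standard_normal((30, 12))
        var = X.var(axis=0, ddof=1)
        oracle = sorted(sorted(range(12), key=lambda j: (-var[j], j))[:5])
        assert naive_variance_screen(X, 5).tolist() == oracle


class TestRunWorkflow:
    def test_pipeline_outputs(self):
        ds = generate(n=120, p=40, model="cox_linear", seed=17)
        res = run_workflow(ds.X, ds.samples, d=15, cv_folds=5, seed=17)
        assert res["selected_columns"].size == 15
        assert res["train_idx"].size + res["test_idx"].size == 120
        assert set(np.unique(res["train_groups"])) <= {"high", "low"}
        assert 0 <= res["test_logrank_p"] <= 1
        # cutoff is the training median
        assert res["cutoff"] == pytest.approx(float(np.median(res["train_scores"])))
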