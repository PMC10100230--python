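import itertools
import math

import numpy as np
import pytest

from esis import (
    KernelConfig,
    SurvivalSamples,
    default_d,
    eccfic_corr,
    ecdf_transform,
    esis_scores,
    km_cdf,
    screen,
    select_top,
)

from conftest import random_survival


class TestEsisScores:
    def test_monotone_transform_invariance_bitwise(self, rng):
        s = random_survival(rng, 40)
        X = rng.standard_normal((40, 6))
        X2 = X.copy()
        X2[:, 0] = 2.0 * X2[:, 0] + 3.0
        X2[:, 3] = np.exp(X2[:, 3])
        assert np.array_equal(esis_scores(X, s), esis_scores(X2, s))

    def test_column_permutation_equivariance(self, rng):
        s = random_survival(rng, 35)
        X = rng.standard_normal((35, 8))
        perm = rng.permutation(8)
        np.testing.assert_array_equal(esis_scores(X[:, perm], s), esis_scores(X, s)[perm])

    def test_duplicated_columns_get_identical_scores(self, rng):
        s = random_survival(rng, 30)
        X = rng.standard_normal((30, 3))
        w = esis_scores(np.hstack([X, X[:, [1]]]), s)
        assert w[3] == w[1]

    def test_constant_column_flagged_not_dropped(self, rng):
        s = random_survival(rng, 25)
        X = rng.standard_normal((25, 4))
        X[:, 2] = 7.0
        w = esis_scores(X, s)
        assert w[2] == -np.inf and np.all(np.isfinite(np.delete(w, 2)))
        res = select_top(w, 4)
        assert res.failed.tolist() == [False, False, True, False]

    def test_matches_single_pair_estimator(self, rng):
        # the batched screen must agree with eccfic_corr gene by gene, bitwise
        s = random_survival(rng, 30)
        X = rng.standard_normal((30, 5))
        _, u = km_cdf(s)
        w = esis_scores(X, s)
        for j in range(5):
            assert w[j] == eccfic_corr(u, ecdf_transform(X[:, j])).rho

    def test_outcome_gene_scores_highest_over_all_permutations(self):
        # with all events and the gene equal to Y itself, no relabelling of the
        # gene values across samples can score higher (n=6: all 720 checked)
        y = np.array([3.0, 1.0, 4.0, 2.0, 6.0, 5.0])
        s = SurvivalSamples(y, np.ones(6, dtype=int))
        _, u = km_cdf(s)
        own = eccfic_corr(u, ecdf_transform(y)).rho
        best = max(
            eccfic_corr(u, ecdf_transform(np.array(p))).rho
            for p in itertools.permutations(y)
        )
        assert own == pytest.approx(best, abs=1e-12)

    def test_noise_genes_score_near_zero(self):
        rng = np.random.default_rng(11)
        s = random_survival(rng, 300)
        X = rng.standard_normal((300, 20))
        assert abs(np.mean(esis_scores(X, s))) < 0.05

    def test_requires_events(self, rng):
        s = SurvivalSamples([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            esis_scores(rng.standard_normal((3, 2)), s)


class TestDefaultD:
    @pytest.mark.parametrize(
        "n,rule,expected",
        [
            (379, "n_minus_1", 378),
            (3, "n_minus_1", 2),
            (100, "n_over_logn", math.floor(100 / math.log(100))),
            (100, "two_n_over_logn", math.floor(200 / math.log(100))),
            (100, "three_n_over_logn", math.floor(300 / math.log(100))),
        ],
    )
    def test_rules(self, n, rule, expected):
        assert default_d(n, rule) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            default_d(1, "n_minus_1")
        with pytest.raises(ValueError):
            default_d(10, "bogus")


class TestSelectTop:
    def test_tie_break_by_column_index(self):
        res = select_top([0.2, 0.9, 0.9, 0.1], 2)
        assert res.selected.tolist() == [1, 2]

    def test_d_equals_p_selects_all(self, rng):
        scores = rng.random(7)
        assert sorted(select_top(scores, 7).selected.tolist()) == list(range(7))

    def test_agrees_with_sort_oracle(self, rng):
        scores = rng.random(50)
        res = select_top(scores, 3)
        oracle = sorted(range(50), key=lambda j: (-scores[j], j))[:3]
        assert res.selected.tolist() == oracle

    def test_d_out_of_range(self, rng):
        with pytest.raises(ValueError):
            select_top(rng.random(5), 6)


class TestScreen:
    def test_end_to_end_contract(self, rng):
        s = random_survival(rng, 50)
        X = rng.standard_normal((50, 30))
        res = screen(X, s, d_rule="n_over_logn")
        assert res.d == default_d(50)
        assert res.selected.tolist() == res.order[: res.d].tolist()
        assert np.array_equal(np.sort(res.order), np.arange(30))
        assert res.selected_ids.shape == (res.d,)
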