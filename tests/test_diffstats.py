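"""Variance-adaptive t machinery, permutation p-values, BH and q-values."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from pathclust.diffstats import (
    DegenerateInputError,
    SignificanceCutoffs,
    adaptive_t,
    bh_adjust,
    declare_significant,
    differential_test,
    f_variance_test,
    permutation_test,
    storey_qvalue,
    student_t,
    welch_t,
)
from tests.conftest import SAMPLE_X, SAMPLE_Y


class TestScalarTests:
    def test_f_test_worked_example(self):
        out = f_variance_test(SAMPLE_X, SAMPLE_Y)
        assert out.statistic == pytest.approx(0.2122, abs=5e-5)
        assert out.pvalue == pytest.approx(0.1141, abs=5e-5)

    def test_f_test_identical_samples(self):
        out = f_variance_test(SAMPLE_X, SAMPLE_X)
        assert out.statistic == 1.0
        assert out.pvalue == pytest.approx(1.0)

    def test_f_test_derived_small_case(self):
        # s1^2 = 1, s2^2 = 4 by hand; p from the F(2, 2) distribution
        out = f_variance_test([1, 2, 3], [2, 4, 6])
        assert out.statistic == pytest.approx(0.25)
        expected_p = 2 * stats.f.cdf(0.25, 2, 2)
        assert out.pvalue == pytest.approx(expected_p, rel=1e-12)

    def test_f_test_zero_variance(self):
        with pytest.raises(DegenerateInputError):
            f_variance_test([1.0, 1.0, 1.0], [1, 2, 3])

    def test_pooled_t_worked_example(self):
        out = student_t(SAMPLE_X, SAMPLE_Y)
        assert out.statistic == pytest.approx(1.959, abs=5e-4)
        assert out.df == 10
        assert out.pvalue == pytest.approx(0.0786, abs=5e-4)
        assert out.pooled_sd == pytest.approx(math.sqrt(0.007055), abs=1e-6)

    def test_pooled_t_identical_samples(self):
        out = student_t([1, 2, 3], [1, 2, 3])
        assert out.statistic == 0.0
        assert out.pvalue == 1.0

    def test_pooled_t_derived_small_case(self):
        out = student_t([1, 2, 3], [4, 5, 6])
        # pooled s^2 = 1, SE = sqrt(2/3)
        assert out.statistic == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
        assert out.df == 4
        assert out.pvalue == pytest.approx(2 * stats.t.sf(abs(out.statistic), 4))

    def test_welch_worked_example(self):
        out = welch_t(SAMPLE_X, SAMPLE_Y)
        assert out.statistic == pytest.approx(1.959, abs=5e-4)
        assert out.pvalue == pytest.approx(0.091, abs=5e-4)
        assert out.df == pytest.approx(7.03, abs=5e-3)

    def test_welch_statistic_equals_pooled_at_equal_n(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0, 3, 8)
        assert welch_t(x, y).statistic == pytest.approx(student_t(x, y).statistic)
        assert welch_t(x, y).df < student_t(x, y).df

    def test_adaptive_chooses_pooled_on_worked_example(self):
        out = adaptive_t(SAMPLE_X, SAMPLE_Y, f_alpha=0.05)
        assert out.branch == "pooled"
        assert out.pvalue == pytest.approx(0.0786, abs=5e-4)
        assert out.f_test.pvalue == pytest.approx(0.1141, abs=5e-5)

    def test_adaptive_switches_to_welch_on_variance_ratio(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 10, 10)
        f = f_variance_test(x, y)
        assert f.pvalue < 0.05  # sanity for this seed
        assert adaptive_t(x, y).branch == "welch"

    def test_adaptive_identical_samples(self):
        out = adaptive_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.branch == "pooled"
        assert out.statistic == 0.0


def _brute_force_permutation_p(x, y, f_alpha=0.05):
    """Exhaustive enumeration oracle: adaptive-t p for every relabelling."""
    pooled = list(x) + list(y)
    n1 = len(x)
    obs = adaptive_t(x, y, f_alpha=f_alpha).pvalue
    count, total = 0, 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        try:
            p = adaptive_t(g1, g2, f_alpha=f_alpha).pvalue
        except DegenerateInputError:
            p = 1.0
        total += 1
        if p <= obs + 1e-12:
            count += 1
    return count / total


class TestPermutationTest:
    def test_exhaustive_matches_enumeration_oracle(self):
        x, y = [0.0, 1.0], [10.0, 11.0]
        res = permutation_test(x, y, B=100, seed=0)
        assert res.exhaustive and res.n_permutations == 6
        assert res.permutation_p == pytest.approx(_brute_force_permutation_p(x, y))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exhaustive_oracle_equality_random_data(self, n, rng):
        x = rng.normal(0, 1, n)
        y = rng.normal(1, 1.5, n)
        res = permutation_test(x, y, B=10_000, seed=1)
        assert res.exhaustive
        assert res.permutation_p == pytest.approx(
            _brute_force_permutation_p(list(x), list(y))
        )

    def test_weakest_observed_statistic_gives_p_one(self):
        res = permutation_test([1.0, 2.0], [2.0, 1.0], B=50, seed=0)
        assert res.permutation_p == 1.0

    def test_deterministic_for_fixed_seed(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1, 9)
        a = permutation_test(x, y, B=300, seed=42)
        b = permutation_test(x, y, B=300, seed=42)
        assert a.permutation_p == b.permutation_p
        assert a.branch_counts == b.branch_counts

    def test_plus_one_estimator_never_returns_zero(self, rng):
        x = rng.normal(0, 0.1, 8)
        y = rng.normal(50, 0.1, 8)
        plain = permutation_test(x, y, B=200, seed=3, estimator="plain")
        plus = permutation_test(x, y, B=200, seed=3, estimator="plus-one")
        assert plus.permutation_p > 0
        assert plus.permutation_p == pytest.approx(
            (1 + plain.permutation_p * plain.n_permutations) / (1 + plain.n_permutations)
        )

    def test_replicates_move_with_their_individual(self):
        """With unit blocks the number of distinct relabellings counts
        individuals, not columns."""
        x = [1.0, 1.1, 2.0, 2.1, 3.0, 3.1]
        y = [5.0, 5.1, 6.0, 6.1]
        res = permutation_test(
            x,
            y,
            B=10_000,
            seed=0,
            units_x=["a", "a", "b", "b", "c", "c"],
            units_y=["d", "d", "e", "e"],
        )
        assert res.exhaustive
        assert res.n_permutations == math.comb(5, 3)

    def test_rejects_tiny_input(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0], B=10)


class TestMultipleTesting:
    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_bh_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_dominates_raw(self, rng):
        p = rng.uniform(0, 1, 60)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_qvalues_equal_bh_when_pi0_forced_to_one(self, rng):
        p = rng.uniform(0, 1, 200)
        q, pi0 = storey_qvalue(p, pi0=1.0)
        assert pi0 == 1.0
        assert np.allclose(q, bh_adjust(p))

    def test_pi0_near_one_under_uniform_null(self):
        # the pi0 estimator at lambda_max has sampling sd ~ 0.1 at m = 1000,
        # so average over independent null draws before asserting the band
        estimates = []
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(0, 1, 1000)
            _, pi0 = storey_qvalue(p)
            assert 0.0 < pi0 <= 1.0
            estimates.append(pi0)
        assert 0.85 <= float(np.mean(estimates)) <= 1.0

    def test_pi0_fallback_below_100_tests(self, rng):
        _, pi0 = storey_qvalue(rng.uniform(0, 1, 50))
        assert pi0 == 1.0

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 500)
        q, _ = storey_qvalue(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_q_shrinks_under_signal(self, rng):
        p = np.concatenate([rng.uniform(0, 0.001, 300), rng.uniform(0, 1, 700)])
        q, pi0 = storey_qvalue(p)
        assert pi0 < 1.0
        assert np.all(q <= bh_adjust(p) + 1e-12)


class TestDeclareSignificant:
    def test_empty_input(self):
        import pandas as pd

        out = declare_significant(pd.DataFrame({"protein_id": [], "q": []}))
        assert all(len(v["proteins"]) == 0 for v in out.values())
        assert all(v["expected_false_positives"] == 0 for v in out.values())

    def test_expected_false_positive_formula(self):
        import pandas as pd

        table = pd.DataFrame(
            {"protein_id": [f"p{i}" for i in range(60)], "q": [0.05] * 50 + [0.5] * 10}
        )
        out = declare_significant(table)
        assert len(out[2]["proteins"]) == 50
        assert out[2]["expected_false_positives"] == pytest.approx(0.1 * 50)

    def test_nested_sets_for_random_q(self, rng):
        import pandas as pd

        table = pd.DataFrame(
            {"protein_id": [f"p{i}" for i in range(200)], "q": rng.uniform(0, 1, 200)}
        )
        out = declare_significant(table)
        assert out[3]["proteins"] <= out[2]["proteins"] <= out[1]["proteins"]

    def test_cutoffs_must_decrease(self):
        with pytest.raises(ValueError):
            SignificanceCutoffs((0.05, 0.1, 0.2))


class TestDifferentialTest:
    def test_batch_and_per_protein_paths_agree_on_observed_stats(self, small_cohort):
        from pathclust.quantify import quantile_normalize

        matrix, ann, _ = small_cohort
        norm = quantile_normalize(matrix)
        a = differential_test(norm, ann, "LuminalA", B=150, seed=5)
        b = differential_test(
            norm, ann, "LuminalA", B=150, seed=5, share_permutations=True
        )
        assert np.allclose(a["t"], b["t"], equal_nan=True)
        assert np.allclose(a["p_obs"], b["p_obs"])
        assert (a["branch"] == b["branch"]).all()
        # Monte-Carlo streams differ but the estimates agree closely
        assert np.corrcoef(a["p_perm"], b["p_perm"])[0, 1] > 0.98

    def test_recovers_planted_proteins(self, small_cohort):
        from pathclust.quantify import quantile_normalize

        matrix, ann, truth = small_cohort
        norm = quantile_normalize(matrix)
        table = differential_test(norm, ann, "LuminalA", B=300, seed=9)
        sig = declare_significant(table)
        planted = truth.differential["LuminalA"]
        # at n=5 patients some planted proteins legitimately lack power;
        # the screen should still find a good share and nothing much else
        recovered = sig[1]["proteins"] & planted
        assert len(recovered) >= 0.4 * len(planted)
        false_hits = sig[1]["proteins"] - planted
        assert len(false_hits) <= 0.2 * 80
        q = table.set_index("protein_id")["q"]
        assert q.loc[sorted(planted)].median() < q.drop(sorted(planted)).median()
        assert table["p_bh"].ge(table["p_perm"] - 1e-15).all()
        assert table["q"].le(table["p_bh"] + 1e-12).all()
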