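"""Cohort statistics against independent oracles.

Every nontrivial statistic is cross-checked against a from-scratch
computation: sign-assignment enumeration for the exact Wilcoxon test,
fixed-margin table enumeration for the Fisher exact test, a spreadsheet-style
worked example for Gwet's AC2, and a hand-rolled Newton-Raphson fit of the
logistic likelihood for the air threshold.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dwidistort import (fisher_exact_2x2, gwet_ac2, logistic_air_threshold,
                        median_iqr, subgroup_compare, wilcoxon_signed_rank)
from dwidistort.stats import interpret_agreement


class TestMedianIqr:
    def test_odd_run(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_constant(self):
        assert median_iqr([2, 2, 2]) == (2.0, 2.0, 2.0)

    def test_matches_sorted_array_brute_force(self, rng):
        x = rng.uniform(0, 1, 1000)
        med, q1, q3 = median_iqr(x)

        def quantile(sorted_x, p):
            h = (len(sorted_x) - 1) * p
            lo = math.floor(h)
            hi = min(lo + 1, len(sorted_x) - 1)
            return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])

        s = np.sort(x)
        assert med == quantile(s, 0.5)
        assert q1 == quantile(s, 0.25)
        assert q3 == quantile(s, 0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


def wilcoxon_enumeration_p(d):
    """Exact two-sided p by brute force over all 2^n sign assignments."""
    d = np.asarray(d, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    t_obs = ranks[d > 0].sum()
    stats = [np.asarray(signs).dot(ranks)
             for signs in itertools.product([0, 1], repeat=len(d))]
    stats = np.asarray(stats)
    p = 2 * min((stats <= t_obs + 1e-12).mean(), (stats >= t_obs - 1e-12).mean())
    return min(p, 1.0)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(RuntimeWarning):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        d = rng.normal(0.3, 1.0, n)
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_antisymmetric_flip_preserves_p(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.4, 1, 12)
        assert (wilcoxon_signed_rank(a, b).p_value
                == pytest.approx(wilcoxon_signed_rank(b, a).p_value))

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.normal(0, 1, 60)
        b = a + rng.normal(0.2, 0.5, 60)
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "approx"
        assert 0.0 <= res.p_value <= 1.0


def fisher_enumeration_p(table):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)
        assert fisher_enumeration_p([[3, 0], [0, 3]]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_fixed_margin_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 12, (2, 2))
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_enumeration_p(table), abs=1e-9)

    def test_transpose_and_row_swap_invariance(self, rng):
        table = rng.integers(0, 15, (2, 2))
        p = fisher_exact_2x2(table)
        assert fisher_exact_2x2(table.T) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(table[::-1]) == pytest.approx(p, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])


# Ten-subject worked example on a 4-point scale, computed by hand:
# ratings (r1, r2): six exact agreements, four one-step disagreements.
# quadratic weights (q=4): w(|d|)=1-(d/3)^2 -> 1, 8/9, 5/9, 0
# p_a = (6*1 + 4*(8/9))/10 = 43/45
# propensities pi = avg over raters: (0.25, 0.30, 0.25, 0.20)
# T_w = 4 + 6*(8/9) + 4*(5/9) + 2*0 = 104/9
# p_e = T_w/(q(q-1)) * sum pi(1-pi) = (104/108) * 0.745 = 1937/2700
# AC2 = (43/45 - 1937/2700)/(1 - 1937/2700) = 643/763
WORKED_RATINGS = [(1, 1), (2, 2), (3, 3), (4, 4), (1, 2),
                  (2, 3), (4, 3), (1, 1), (2, 2), (3, 4)]
WORKED_AC2 = 643.0 / 763.0


class TestGwetAc2:
    def test_perfect_agreement_is_one(self):
        ratings = [(s, s) for s in (1, 2, 3, 4, 1, 2)]
        res = gwet_ac2(ratings, categories=[1, 2, 3, 4])
        assert res.coefficient == pytest.approx(1.0)
        assert res.benchmark == "almost perfect"

    def test_worked_example_to_1e9(self):
        res = gwet_ac2(WORKED_RATINGS, categories=[1, 2, 3, 4])
        assert res.p_observed == pytest.approx(43.0 / 45.0, abs=1e-12)
        assert res.p_expected == pytest.approx(1937.0 / 2700.0, abs=1e-12)
        assert res.coefficient == pytest.approx(WORKED_AC2, abs=1e-9)

    def test_noise_degrades_agreement_monotonically(self):
        scale = np.arange(1, 6)
        levels = [0.0, 0.2, 0.5]
        means = []
        for noise in levels:
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                r1 = rng.integers(1, 6, 40)
                flip = rng.random(40) < noise
                r2 = np.where(flip, rng.integers(1, 6, 40), r1)
                vals.append(gwet_ac2(np.column_stack([r1, r2]),
                                     categories=scale).coefficient)
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(1.0)
        assert means[0] > means[1] > means[2]

    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)),
                    min_size=2, max_size=30))
    def test_bounded_in_minus_one_one(self, ratings):
        res = gwet_ac2(ratings, categories=[1, 2, 3, 4, 5])
        assert -1.0 - 1e-12 <= res.coefficient <= 1.0 + 1e-12

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            gwet_ac2(np.ones((5, 1)))

    def test_benchmark_bands(self):
        assert interpret_agreement(0.9) == "almost perfect"
        assert interpret_agreement(0.7) == "substantial"
        assert interpret_agreement(-0.1) == "poor"


def newton_raphson_logistic(x, y, iters=200):
    """Independent IRLS/Newton fit of P(y=1) = sigmoid(b0 + b1 x)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(iters):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        w = p * (1 - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


class TestLogisticThreshold:
    def test_perfect_separation_reports_midpoint(self):
        vols = np.arange(1.0, 11.0)
        labels = (vols > 5.5).astype(int)
        res = logistic_air_threshold(vols, labels)
        assert res.separated
        assert res.v_thresh_air == pytest.approx(5.5)

    def test_recovers_generative_crossover(self):
        rng = np.random.default_rng(42)
        air = rng.lognormal(np.log(3.0), 0.9, 200)
        p = 1.0 / (1.0 + np.exp(-(air - 4.0) / 1.0))
        labels = (rng.random(200) < p).astype(int)
        res = logistic_air_threshold(air, labels)
        assert not res.separated
        assert res.v_thresh_air == pytest.approx(4.0, abs=0.5)
        assert res.p_value < 0.001

    def test_matches_newton_raphson_oracle(self):
        rng = np.random.default_rng(3)
        air = rng.uniform(0, 10, 80)
        labels = (rng.random(80) < 1 / (1 + np.exp(-(air - 5)))).astype(int)
        res = logistic_air_threshold(air, labels)
        b0, b1 = newton_raphson_logistic(air, labels)
        assert res.beta0 == pytest.approx(b0, abs=1e-6)
        assert res.beta1 == pytest.approx(b1, abs=1e-6)
        assert res.v_thresh_air == pytest.approx(-b0 / b1, abs=1e-6)

    def test_single_class_rejected(self):
        from dwidistort.errors import DegenerateInputError
        with pytest.raises(DegenerateInputError):
            logistic_air_threshold(np.arange(10.0), np.zeros(10, int))

    def test_decreasing_relationship_rejected(self):
        vols = np.arange(1.0, 13.0)
        labels = (vols < 5).astype(int)
        with pytest.raises(ValueError):
            logistic_air_threshold(vols, labels)


def toy_cohort(n=12):
    rng = np.random.default_rng(5)
    air = rng.uniform(0, 8, n)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "air_supine_cm3": air,
        "air_prone_cm3": air * 0.5,
        "distortion_supine_mm": rng.uniform(2, 5, n),
        "distortion_prone_mm": rng.uniform(2, 5, n),
        "likert_supine": rng.integers(1, 6, n),
        "likert_prone": rng.integers(1, 6, n),
    })


class TestSubgroupCompare:
    def test_identical_positions_give_p_one_and_equal_medians(self):
        df = toy_cohort()
        df["air_prone_cm3"] = df["air_supine_cm3"]
        df["distortion_prone_mm"] = df["distortion_supine_mm"]
        df["likert_prone"] = df["likert_supine"]
        summary = subgroup_compare(df, v_thresh=4.0)
        for comp in summary.whole:
            assert comp.p_value == 1.0
            assert comp.supine_median == comp.prone_median

    def test_threshold_above_all_volumes_not_evaluable(self):
        summary = subgroup_compare(toy_cohort(), v_thresh=100.0)
        assert summary.n_subgroup == 0
        assert all(not c.evaluable for c in summary.subgroup)

    def test_scatter_is_long_format(self):
        summary = subgroup_compare(toy_cohort(), v_thresh=4.0)
        assert len(summary.scatter) == 24
        assert set(summary.scatter["position"]) == {"supine", "prone"}
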