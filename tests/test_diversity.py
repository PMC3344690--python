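"""Diversity measures: worked examples frozen from exact fraction arithmetic,
plus the structural properties of the f-diversity family."""

import math
from fractions import Fraction

import numpy as np
import pytest

from fdiversity import (
    JointDistribution,
    ProbabilityDistribution,
    diversity_from_rarity,
    f_entropy,
    f_information,
    gini_simpson_diversity,
    marginal_f_diversity,
    number_of_categories_diversity,
    rarity_order_beta,
    relative_f_diversity,
    relative_marginal_diversity,
    relative_self_diversity,
    self_f_diversity,
    shannon_diversity,
)
from conftest import random_distributions


def dist(*counts):
    return ProbabilityDistribution.from_counts(
        [f"c{i}" for i in range(len(counts))], counts)


def exact_gs(*counts):
    """Independent oracle: Gini-Simpson index in exact rational arithmetic."""
    total = sum(counts)
    return float(1 - sum(Fraction(c, total) ** 2 for c in counts))


class TestGiniSimpson:
    @pytest.mark.parametrize("counts, expected", [
        ((27, 63, 0), 0.42),        # allergy narrative sample
        ((15, 0, 19, 37), float(Fraction(3086, 5041))),  # smoking narrative
        ((1,), 0.0),
        ((1, 1), 0.5),
    ])
    def test_values(self, counts, expected):
        assert gini_simpson_diversity(dist(*counts)) == pytest.approx(
            expected, abs=1e-12)
        assert exact_gs(*counts) == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_maximum_at_uniform(self):
        for p in random_distributions(50, seed=3):
            h = gini_simpson_diversity(p)
            hmax = (p.k - 1) / p.k
            assert 0.0 <= h <= hmax + 1e-12
            if np.ptp(p.probs) > 1e-9:
                assert h < hmax - 0.0  # strictly below unless uniform
        u = ProbabilityDistribution.uniform(list("abcd"))
        assert gini_simpson_diversity(u) == pytest.approx(0.75, abs=1e-12)


class TestShannon:
    @pytest.mark.parametrize("probs, base, expected", [
        ((1.0,), math.e, 0.0),
        ((0.5, 0.5), math.e, math.log(2)),
        ((0.8, 0.2), 2, -(0.8 * math.log2(0.8) + 0.2 * math.log2(0.2))),
    ])
    def test_values(self, probs, base, expected):
        p = ProbabilityDistribution([f"c{i}" for i in range(len(probs))], probs)
        assert shannon_diversity(p, base) == pytest.approx(expected, abs=1e-12)

    def test_zero_categories_contribute_nothing(self):
        assert shannon_diversity(dist(1, 0, 1)) == pytest.approx(math.log(2))

    def test_bounds_and_maximum_at_uniform(self):
        for p in random_distributions(50, seed=4):
            h = shannon_diversity(p)
            assert -1e-12 <= h <= math.log(p.k) + 1e-12


class TestNumberOfCategories:
    def test_counts_labels_not_support(self):
        # zero-probability categories still count toward k
        assert number_of_categories_diversity(dist(15, 0, 19, 37)) == 3
        assert number_of_categories_diversity(dist(5)) == 0

    def test_thirty_observed_terms(self):
        p = ProbabilityDistribution.uniform([f"t{i}" for i in range(30)])
        assert number_of_categories_diversity(p) == 29


class TestFEntropy:
    def test_gs_generator_reproduces_index(self, gs):
        for p in random_distributions(30, seed=5):
            assert f_entropy(gs, p) == pytest.approx(
                gini_simpson_diversity(p), abs=1e-12)

    def test_shannon_generator_reproduces_entropy(self, shannon):
        p = dist(1, 1, 1, 1)
        assert f_entropy(shannon, p) == pytest.approx(math.log(4), abs=1e-12)
        for q in random_distributions(30, seed=6):
            assert f_entropy(shannon, q) == pytest.approx(
                shannon_diversity(q), abs=1e-12)

    def test_noc_generator_gives_k_minus_one(self, noc):
        for p in random_distributions(30, seed=7, min_p=1e-6):
            assert f_entropy(noc, p) == pytest.approx(p.k - 1, rel=1e-9)

    def test_smoking_narrative_value(self, gs):
        assert f_entropy(gs, dist(15, 0, 19, 37)) == pytest.approx(
            exact_gs(15, 0, 19, 37), abs=1e-12)

    def test_concavity_on_mixtures(self, gs, shannon, noc):
        rng = np.random.default_rng(8)
        for f in (gs, shannon, noc):
            for p, q in zip(random_distributions(10, seed=9, min_p=1e-4),
                            random_distributions(10, seed=10, min_p=1e-4)):
                if p.k != q.k:
                    continue
                lam = float(rng.uniform(0.05, 0.95))
                mix = ProbabilityDistribution(
                    p.labels, lam * p.probs + (1 - lam) * q.probs)
                lhs = f_entropy(f, mix)
                rhs = lam * f_entropy(f, p) + (1 - lam) * f_entropy(f, q)
                assert lhs >= rhs - 1e-10


class TestRelativeFDiversity:
    def test_smoking_narrative(self, gs):
        expected = float(Fraction(3086, 5041) / Fraction(3, 4))
        assert relative_f_diversity(gs, dist(15, 0, 19, 37)) == pytest.approx(
            expected, abs=1e-12)
        assert round(expected, 4) == 0.8162

    def test_ischemic_structured(self, gs):
        expected = float(exact_gs(44, 992, 9) / Fraction(2, 3))
        assert relative_f_diversity(gs, dist(44, 992, 9)) == pytest.approx(
            expected, abs=1e-12)
        assert round(expected, 4) == 0.1455

    def test_uniform_is_one(self, gs, shannon):
        for k in (2, 3, 7):
            u = ProbabilityDistribution.uniform([f"c{i}" for i in range(k)])
            assert relative_f_diversity(gs, u) == pytest.approx(1.0, abs=1e-12)
            assert relative_f_diversity(shannon, u) == pytest.approx(1.0, abs=1e-12)

    def test_single_category_is_zero(self, gs):
        assert relative_f_diversity(gs, dist(5)) == 0.0

    def test_in_unit_interval(self, gs, shannon):
        for p in random_distributions(30, seed=11):
            for f in (gs, shannon):
                assert -1e-12 <= relative_f_diversity(f, p) <= 1 + 1e-12


class TestOrderBetaRarity:
    @pytest.mark.parametrize("beta, p, expected", [
        (1.0, 0.3, 0.7),                 # Gini-Simpson rarity 1 - p
        (-1.0, 0.25, 3.0),               # number-of-categories rarity (1-p)/p
        (0.0, 0.5, math.log(2)),         # Shannon rarity -log p
    ])
    def test_special_cases(self, beta, p, expected):
        assert rarity_order_beta(p, beta) == pytest.approx(expected, abs=1e-12)

    def test_pointwise_collapse_on_grid(self):
        for p in np.linspace(0.01, 1.0, 25):
            assert rarity_order_beta(p, 1.0) == pytest.approx(1 - p, abs=1e-12)
            assert rarity_order_beta(p, 0.0) == pytest.approx(-math.log(p), abs=1e-12)
            assert rarity_order_beta(p, -1.0) == pytest.approx((1 - p) / p, rel=1e-12)

    def test_zero_probability_signals_infinity(self):
        assert math.isinf(rarity_order_beta(0.0, 0.0))
        assert math.isinf(rarity_order_beta(0.0, -1.0))
        assert rarity_order_beta(0.0, 1.0) == 1.0

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            rarity_order_beta(0.5, -2.0)
        with pytest.raises(ValueError):
            rarity_order_beta(1.5, 1.0)


class TestDiversityFromRarity:
    def test_gs_rarities(self):
        p = dist(2, 3, 5)
        r = 1 - p.probs
        assert diversity_from_rarity(p, r) == pytest.approx(
            gini_simpson_diversity(p), abs=1e-12)

    def test_noc_rarities(self):
        p = dist(2, 3, 5)
        r = (1 - p.probs) / p.probs
        assert diversity_from_rarity(p, r) == pytest.approx(2.0, abs=1e-12)

    def test_shannon_rarities(self):
        p = ProbabilityDistribution(["a", "b"], [0.6, 0.4])
        r = -np.log(p.probs)
        expected = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4))
        assert diversity_from_rarity(p, r) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.673012, abs=5e-7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            diversity_from_rarity(dist(1, 1), [1.0, 1.0, 1.0])


class TestSelfDiversity:
    def test_gs_is_complement_probability(self, gs):
        p = dist(15, 0, 19, 37)  # smoking narrative
        assert self_f_diversity(gs, p, 0) == pytest.approx(56 / 71, abs=1e-9)
        assert round(self_f_diversity(gs, p, 0), 4) == 0.7887
        assert self_f_diversity(gs, p, 1) == pytest.approx(1.0, abs=1e-9)

    def test_shannon_is_self_information(self, shannon):
        p = ProbabilityDistribution(["a", "b"], [1.0, 0.0])
        assert self_f_diversity(shannon, p, 0) == pytest.approx(0.0, abs=1e-12)
        assert math.isinf(self_f_diversity(shannon, p, 1))

    def test_representation_identity(self, gs, shannon, noc):
        # H_f(p) is the p-weighted average of the self f-diversities
        for p in random_distributions(200, seed=12, min_p=1e-9):
            for f in (gs, shannon, noc):
                total = sum(p.probs[i] * self_f_diversity(f, p, i)
                            for i in range(p.k))
                assert total == pytest.approx(f_entropy(f, p), abs=1e-10)

    def test_gs_self_diversities_sum_to_k_minus_one(self, gs):
        for p in random_distributions(50, seed=13):
            s = sum(self_f_diversity(gs, p, i) for i in range(p.k))
            assert s == pytest.approx(p.k - 1, abs=1e-9)

    def test_strictly_decreasing_in_probability(self, gs):
        grid = np.linspace(0.05, 0.95, 10)
        vals = []
        for pi in grid:
            p = ProbabilityDistribution(["a", "b"], [pi, 1 - pi])
            vals.append(self_f_diversity(gs, p, 0))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMarginalDiversity:
    @pytest.mark.parametrize("pi, expected", [
        (0.5, 0.5),
        (0.0, 0.0),
        (1.0, 0.0),
    ])
    def test_gs_dichotomy(self, gs, pi, expected):
        p = ProbabilityDistribution(["a", "b"], [pi, 1 - pi])
        assert marginal_f_diversity(gs, p, 0) == pytest.approx(expected, abs=1e-12)

    def test_gs_equals_two_p_q(self, gs):
        for p in random_distributions(20, seed=14):
            for i in range(p.k):
                pi = p.probs[i]
                assert marginal_f_diversity(gs, p, i) == pytest.approx(
                    2 * pi * (1 - pi), abs=1e-12)

    def test_shannon_binary_entropy(self, shannon):
        p = dist(1, 3)
        expected = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        assert marginal_f_diversity(shannon, p, 0) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.562335, abs=5e-7)


class TestRelativeSelfAndMarginal:
    def test_relative_self_even_dichotomy(self, gs):
        assert relative_self_diversity(gs, dist(1, 1), 0) == pytest.approx(1.0)

    def test_relative_self_smoking_smoker(self, gs):
        # (56/71) / (3086/5041), exact-fraction oracle
        expected = float(Fraction(56, 71) / Fraction(3086, 5041))
        assert relative_self_diversity(gs, dist(15, 0, 19, 37), 0) == \
            pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.288399, abs=5e-7)

    def test_relative_self_uniform_is_one(self, gs):
        u = ProbabilityDistribution.uniform(list("abcde"))
        for i in range(5):
            assert relative_self_diversity(gs, u, i) == pytest.approx(1.0)

    def test_relative_self_undefined_at_zero_diversity(self, gs):
        with pytest.raises(ValueError):
            relative_self_diversity(gs, dist(7), 0)

    def test_relative_marginal_gs_is_4pq(self, gs):
        p = dist(730, 350)  # nonsmoker structured dichotomy
        expected = float(4 * Fraction(730, 1080) * Fraction(350, 1080))
        assert relative_marginal_diversity(gs, p, 0) == pytest.approx(
            expected, abs=1e-12)
        assert round(expected, 4) == 0.8762

    def test_relative_marginal_limits(self, gs):
        assert relative_marginal_diversity(gs, dist(1, 1), 0) == pytest.approx(1.0)
        assert relative_marginal_diversity(gs, dist(0, 5), 0) == 0.0

    def test_binary_symmetry(self, gs):
        # both categories of a dichotomy share the same relative marginal value
        for p in random_distributions(30, seed=15, max_k=2):
            a = relative_marginal_diversity(gs, p, 0)
            b = relative_marginal_diversity(gs, p, 1)
            assert a == pytest.approx(b, abs=1e-12)

    def test_increasing_toward_half(self, gs):
        grid = np.linspace(0.02, 0.5, 12)
        vals = [relative_marginal_diversity(
            gs, ProbabilityDistribution(["a", "b"], [x, 1 - x]), 0)
            for x in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestFInformation:
    def test_zero_at_independence(self, gs, shannon):
        px = dist(2, 3)
        py = dist(1, 1, 2)
        j = JointDistribution.independent(px, py)
        for f in (gs, shannon):
            assert f_information(f, j) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_dependence_equals_marginal_entropy(self, shannon):
        j = JointDistribution(["a", "b"], ["a", "b"], [[0.5, 0], [0, 0.5]])
        assert f_information(shannon, j) == pytest.approx(math.log(2), abs=1e-12)

    def test_shannon_mutual_information_value(self, shannon):
        j = JointDistribution(["a", "b"], ["a", "b"], [[0.4, 0.1], [0.1, 0.4]])
        expected = sum(
            pij * math.log(pij / 0.25)
            for pij in (0.4, 0.1, 0.1, 0.4))
        assert f_information(shannon, j) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.192745, abs=5e-7)

    def test_nonnegative_on_random_joints(self, gs, shannon):
        rng = np.random.default_rng(16)
        for _ in range(30):
            m = rng.dirichlet(np.ones(6)).reshape(2, 3)
            j = JointDistribution(["a", "b"], ["x", "y", "z"], m)
            for f in (gs, shannon):
                assert f_information(f, j) >= -1e-12
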