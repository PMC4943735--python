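"""LOO classification, permutation significance, pairwise driver and
unknown-group assignment."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from patdist.distinguish import (
    ClassifierConfig,
    assign_unknowns,
    holm_flags,
    loo_success_rate,
    pairwise_distinguishability,
    permutation_p_value,
)
from patdist.imaging import ValidationError


def separable_data(n_per=5, T=10, gap=1.0, noise=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    X = np.vstack([
        np.zeros((n_per, T)) + noise * rng.standard_normal((n_per, T)),
        np.full((n_per, T), gap) + noise * rng.standard_normal((n_per, T)),
    ])
    labels = ["a"] * n_per + ["b"] * n_per
    return X, labels


class TestLOO:
    def test_perfectly_separable_classes(self):
        X, labels = separable_data()
        res = loo_success_rate(X, labels)
        assert res.success_rate == 1.0
        assert res.n == 10

    def test_rate_times_n_is_integer(self, rng):
        X = rng.standard_normal((12, 6))
        labels = ["a"] * 6 + ["b"] * 6
        res = loo_success_rate(X, labels)
        assert res.success_rate * res.n == pytest.approx(round(res.success_rate * res.n))

    def test_null_mean_success_near_half(self):
        # labels carry no signature information: mean LOO over seeds ~ 0.5
        rates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((20, 8))
            labels = ["a"] * 10 + ["b"] * 10
            rates.append(loo_success_rate(X, labels).success_rate)
        assert 0.35 <= np.mean(rates) <= 0.65

    def test_label_symmetry(self, rng):
        X = rng.standard_normal((14, 5))
        labels = np.array(["a"] * 7 + ["b"] * 7)
        swapped = np.where(labels == "a", "b", "a")
        assert (
            loo_success_rate(X, labels).success_rate
            == loo_success_rate(X, swapped).success_rate
        )

    def test_input_validation(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValidationError):
            loo_success_rate(X, ["a"] * 10)  # single class
        with pytest.raises(ValidationError):
            loo_success_rate(X, ["a"] * 9 + ["b"])  # class with < 2 members
        with pytest.raises(ValidationError):
            loo_success_rate(X, ["a", "b", "c"] * 3 + ["a"])  # > 2 classes
        with pytest.raises(ValidationError):
            loo_success_rate(np.full((10, 4), np.nan), ["a"] * 5 + ["b"] * 5)


class TestPermutation:
    def test_separable_fixture_significant(self):
        # 8 per class: label-preserving permutations (the only ones that
        # can reach the observed rate 1.0) have probability 2/C(16,8),
        # negligible at 199 draws
        X, labels = separable_data(n_per=8)
        res = permutation_p_value(X, labels, n_permutations=199, seed=11)
        assert res.observed_rate == 1.0
        assert res.p_value <= 0.01

    def test_p_value_bounds_and_reproducibility(self, rng):
        X = rng.standard_normal((10, 4))
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permutation_p_value(X, labels, n_permutations=99, seed=5)
        r2 = permutation_p_value(X, labels, n_permutations=99, seed=5)
        assert 1 / 100 <= r1.p_value <= 1.0
        assert np.array_equal(r1.null_rates, r2.null_rates)
        r3 = permutation_p_value(X, labels, n_permutations=99, seed=6)
        assert not np.array_equal(r1.null_rates, r3.null_rates)

    def test_too_few_permutations_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValidationError):
            permutation_p_value(X, ["a"] * 5 + ["b"] * 5, n_permutations=50)

    def test_type_one_error_calibrated(self):
        # independent labels: P(p < 0.05) within the exact binomial 99%
        # band around 0.05 at 100 replicates (the add-one estimator is
        # conservative, so low counts are expected)
        from scipy.stats import binom

        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            X = rng.standard_normal((12, 6))
            labels = ["a"] * 6 + ["b"] * 6
            p = permutation_p_value(X, labels, n_permutations=99, seed=rep).p_value
            hits += p < 0.05
        lo, hi = binom.ppf([0.005, 0.995], reps, 0.05)
        assert 0 <= hits <= hi
        assert hits >= lo or lo == 0


class TestHolm:
    def test_matches_statsmodels_step_down(self, rng):
        for _ in range(5):
            p = rng.random(6) * 0.2
            expected = multipletests(p, alpha=0.05, method="holm")[0]
            assert holm_flags(p, alpha=0.05) == expected.tolist()

    def test_known_sequence_all_significant(self):
        # ordered thresholds 0.05/3, 0.05/2, 0.05/1 -> every p passes
        assert holm_flags([0.001, 0.02, 0.04]) == [True, True, True]
        assert holm_flags([0.001, 0.03, 0.04]) == [True, False, False]


class TestPairwise:
    def test_three_classes_three_pairs(self, rng):
        X = np.vstack([np.zeros((4, 5)), np.ones((4, 5)), np.full((4, 5), 2.0)])
        X += 0.01 * rng.standard_normal(X.shape)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = pairwise_distinguishability(X, labels, n_permutations=99, seed=0)
        assert [r.pair for r in res] == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_coincident_class_not_separable(self, rng):
        far = np.full((8, 6), 5.0)
        a = 0.05 * rng.standard_normal((8, 6))
        coincident = 0.05 * rng.standard_normal((8, 6))
        X = np.vstack([a, far, coincident])
        labels = ["a"] * 8 + ["far"] * 8 + ["twin"] * 8
        res = {r.pair: r.result.p_value for r in pairwise_distinguishability(
            X, labels, n_permutations=199, seed=2)}
        assert res[("a", "far")] <= 0.01
        assert res[("far", "twin")] <= 0.01
        assert res[("a", "twin")] > 0.05

    def test_missing_pair_class_rejected(self, rng):
        X = rng.standard_normal((8, 3))
        with pytest.raises(ValidationError):
            pairwise_distinguishability(
                X, ["a"] * 4 + ["b"] * 4, pairs=[("a", "z")], n_permutations=99
            )


class TestAssign:
    def test_unknowns_identical_to_class_a(self, rng):
        X, labels = separable_data(n_per=5)
        res = assign_unknowns(X, labels, X[:5], n_permutations=99, seed=1)
        assert res.fractions["a"] == 1.0
        assert sum(res.fractions.values()) == pytest.approx(1.0)

    def test_unknowns_from_class_a_distribution(self):
        # unknowns drawn from the same generator as class a: majority
        # assigned a, and the group is not separable from a (p > 0.05)
        # in most replicate runs
        wins = 0
        runs = 10
        for rep in range(runs):
            rng = np.random.default_rng(200 + rep)
            a = rng.standard_normal((8, 6))
            b = rng.standard_normal((8, 6)) + 4.0
            unknowns = rng.standard_normal((10, 6))
            res = assign_unknowns(
                np.vstack([a, b]), ["a"] * 8 + ["b"] * 8, unknowns,
                n_permutations=99, seed=rep,
            )
            ok = res.fractions["a"] > 0.5 and res.group_separability["a"].p_value > 0.05
            wins += ok
        assert wins >= 8

    def test_dimension_mismatch_rejected(self, rng):
        X, labels = separable_data()
        with pytest.raises(ValidationError):
            assign_unknowns(X, labels, rng.standard_normal((3, 7)))
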