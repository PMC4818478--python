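"""Reliability statistics: weights, kappa, percent agreement, ICC, labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icutriage import (
    RatingMatrix,
    UndefinedKappaError,
    icc_average,
    kappa_vs_reference,
    landis_koch_label,
    pairwise_summary,
    percent_agreement,
    quadratic_weights,
    weighted_kappa,
)


def sklearn_kappa(x, y, k):
    """Independent oracle: scikit-learn's quadratic-weighted Cohen's kappa."""
    from sklearn.metrics import cohen_kappa_score

    return cohen_kappa_score(x, y, labels=list(range(1, k + 1)), weights="quadratic")


class TestQuadraticWeights:
    def test_extreme_corner_and_interior_cell(self):
        w = quadratic_weights(4)
        assert w[0, 3] == 0.0
        assert w[1, 2] == pytest.approx(8 / 9)

    def test_two_categories_reduce_to_identity(self):
        assert np.array_equal(quadratic_weights(2), np.eye(2))

    @pytest.mark.parametrize("k", [2, 3, 4, 7])
    def test_symmetric_unit_diagonal(self, k):
        w = quadratic_weights(k)
        assert np.array_equal(w, w.T)
        assert np.array_equal(np.diag(w), np.ones(k))
        assert w.min() == 0.0

    def test_rejects_degenerate_category_count(self):
        with pytest.raises(ValueError):
            quadratic_weights(1)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        assert weighted_kappa([1, 2, 3, 4, 2, 3], [1, 2, 3, 4, 2, 3]) == 1.0

    def test_hand_computed_crossed_table(self):
        # joint table has only (1,2) and (2,1) cells; P_o = 8/9, P_e = 17/18
        assert weighted_kappa([1, 1, 2, 2], [2, 2, 1, 1]) == pytest.approx(-1.0)

    def test_independent_ratings_have_near_zero_kappa(self):
        rng = np.random.default_rng(42)
        x = rng.integers(1, 5, size=10_000)
        y = rng.integers(1, 5, size=10_000)
        assert abs(weighted_kappa(x, y)) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_sklearn_on_random_vectors(self, seed, k):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, k + 1, size=40)
        y = np.where(rng.random(40) < 0.6, x, rng.integers(1, k + 1, size=40))
        assert weighted_kappa(x, y, k) == pytest.approx(sklearn_kappa(x, y, k))

    def test_binary_case_equals_unweighted_cohen_kappa(self):
        # brute force over every pair of binary vectors of length 5
        def cohen_oracle(x, y):
            n = len(x)
            po = sum(a == b for a, b in zip(x, y)) / n
            pe = sum(
                (x.count(c) / n) * (y.count(c) / n) for c in (1, 2)
            )
            return None if pe == 1 else (po - pe) / (1 - pe)

        for x in itertools.product((1, 2), repeat=5):
            for y in itertools.product((1, 2), repeat=5):
                expected = cohen_oracle(list(x), list(y))
                if expected is None:
                    continue
                assert weighted_kappa(x, y, k=2) == pytest.approx(expected)

    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=2, max_size=12))
    def test_symmetry(self, pairs):
        x, y = zip(*pairs)
        try:
            assert weighted_kappa(x, y) == pytest.approx(weighted_kappa(y, x))
        except UndefinedKappaError:
            with pytest.raises(UndefinedKappaError):
                weighted_kappa(y, x)

    def test_missing_positions_dropped_pairwise(self):
        x = [1, 2, np.nan, 3, 4]
        y = [1, 2, 4, np.nan, 4]
        assert weighted_kappa(x, y) == weighted_kappa([1, 2, 4], [1, 2, 4]) == 1.0

    def test_constant_identical_pair_is_one(self):
        assert weighted_kappa([2, 2, 2], [2, 2, 2]) == 1.0

    def test_distinct_constant_raters_agree_at_chance(self):
        # both marginals are point masses on different categories: the weighted
        # observed and chance agreement coincide, so kappa is exactly 0
        assert weighted_kappa([2, 2, 2], [3, 3, 3]) == pytest.approx(0.0)

    def test_requires_two_overlapping_positions(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, np.nan], [np.nan, 1])


class TestPercentAgreement:
    def test_examples(self):
        assert percent_agreement([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert percent_agreement([1, 2, 3, 4], [1, 2, 4, 4]) == 0.75
        assert percent_agreement([1, 1], [2, 2]) == 0.0

    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=1, max_size=12))
    def test_is_one_iff_identical(self, pairs):
        x, y = zip(*pairs)
        p = percent_agreement(x, y)
        assert 0.0 <= p <= 1.0
        assert (p == 1.0) == (x == y)


class TestPairwiseSummary:
    def test_nine_raters_give_36_pairs(self):
        rng = np.random.default_rng(0)
        ratings = pd.DataFrame(rng.integers(1, 5, size=(10, 9)))
        m = RatingMatrix(ratings)
        s = pairwise_summary(m, "percent", n_bootstrap=0)
        assert s.n_pairs == 36

    def test_identical_raters(self):
        ratings = pd.DataFrame({f"r{i}": [1, 2, 3, 4, 2] for i in range(4)})
        s = pairwise_summary(RatingMatrix(ratings), "kappa", n_bootstrap=100, seed=3)
        assert s.median == s.overall == 1.0
        assert s.iqr == (1.0, 1.0)

    def test_overall_is_mean_of_pairwise_oracle_values(self, small_matrix):
        s = pairwise_summary(small_matrix, "kappa", n_bootstrap=0)
        cols = small_matrix.ratings.columns
        expected = [
            sklearn_kappa(small_matrix.ratings[a], small_matrix.ratings[b], 4)
            for a, b in itertools.combinations(cols, 2)
        ]
        assert s.n_pairs == 3
        assert s.overall == pytest.approx(np.mean(expected))
        assert min(expected) <= s.overall <= max(expected)

    def test_bootstrap_ci_brackets_overall_and_is_seeded(self, small_matrix):
        s1 = pairwise_summary(small_matrix, "kappa", n_bootstrap=300, seed=7)
        s2 = pairwise_summary(small_matrix, "kappa", n_bootstrap=300, seed=7)
        assert s1.ci95 == s2.ci95
        lo, hi = s1.ci95
        assert lo <= s1.overall <= hi

    def test_rejects_single_rater(self):
        with pytest.raises(ValueError):
            pairwise_summary(RatingMatrix(pd.DataFrame({"r1": [1, 2, 3]})), "kappa")


class TestKappaVsReference:
    def test_perfect_raters(self, small_matrix):
        ref = small_matrix.reference
        m = RatingMatrix(
            pd.DataFrame({"a": ref, "b": ref}), reference=ref, category_count=4
        )
        s = kappa_vs_reference(m)
        assert s.median == 1.0

    def test_single_rater_summary_is_degenerate(self):
        ref = pd.Series([1, 2, 3, 4])
        m = RatingMatrix(pd.DataFrame({"a": [1, 2, 4, 4]}), reference=ref)
        s = kappa_vs_reference(m)
        assert s.n_pairs == 1
        assert s.median == s.overall
        assert s.iqr == (s.median, s.median)

    def test_requires_reference(self, small_matrix):
        m = RatingMatrix(small_matrix.ratings)
        with pytest.raises(ValueError, match="reference"):
            kappa_vs_reference(m)


class TestIcc:
    def test_identical_raters_and_varying_vignettes(self):
        ratings = pd.DataFrame({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [1, 2, 3, 4]})
        icc, (lo, hi) = icc_average(RatingMatrix(ratings))
        assert icc == pytest.approx(1.0)
        assert hi <= 1.0 + 1e-9

    def test_duplicated_rater_is_perfectly_consistent(self):
        ratings = pd.DataFrame({"a": [1, 3, 2, 4], "b": [1, 3, 2, 4]})
        icc, _ = icc_average(RatingMatrix(ratings))
        assert icc == pytest.approx(1.0)

    def test_matches_hand_mean_squares_oracle_on_4x3_grid(self):
        grid = np.array([[2, 3, 3], [1, 1, 2], [4, 4, 3], [2, 3, 4]], dtype=float)
        n, k = grid.shape
        grand = grid.mean()
        msr = k * ((grid.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ssc = n * ((grid.mean(axis=0) - grand) ** 2).sum()
        sse = ((grid - grand) ** 2).sum() - (n - 1) * msr - ssc
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / msr  # consistency-type, average measures
        icc, _ = icc_average(RatingMatrix(pd.DataFrame(grid, columns=list("abc"))))
        assert icc == pytest.approx(expected)

    def test_icc_recovers_as_noise_shrinks(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(1, 5, size=200).astype(float)
        iccs = []
        for flip_prob in (0.6, 0.3, 0.05):
            cols = {}
            for r in range(4):
                noisy = truth.copy()
                flip = rng.random(truth.size) < flip_prob
                noisy[flip] = rng.integers(1, 5, size=int(flip.sum()))
                cols[f"r{r}"] = noisy
            iccs.append(icc_average(RatingMatrix(pd.DataFrame(cols)))[0])
        assert iccs[0] < iccs[1] < iccs[2]

    def test_listwise_deletion_of_incomplete_vignettes(self):
        ratings = pd.DataFrame(
            {"a": [1, 2, 3, 4, np.nan], "b": [1, 2, 3, 4, 2], "c": [2, 2, 3, 4, 3]}
        )
        complete = RatingMatrix(ratings.dropna())
        assert icc_average(RatingMatrix(ratings)) == icc_average(complete)

    def test_no_subject_variance_is_an_error(self):
        ratings = pd.DataFrame({"a": [2, 2, 2, 2], "b": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="no subject variance"):
            icc_average(RatingMatrix(ratings))

    def test_absolute_agreement_variant_penalizes_rater_offsets(self):
        ratings = pd.DataFrame({"a": [1, 2, 3], "b": [2, 3, 4]})
        m = RatingMatrix(ratings)
        consistency, _ = icc_average(m, model="consistency")
        agreement, _ = icc_average(m, model="agreement")
        assert consistency == pytest.approx(1.0)
        assert agreement < consistency


class TestLandisKoch:
    @pytest.mark.parametrize(
        ("kappa", "label"),
        [
            (-0.2, "poor"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert landis_koch_label(kappa) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            landis_koch_label(1.5)


def test_rating_matrix_validates_cell_range():
    with pytest.raises(ValueError):
        RatingMatrix(pd.DataFrame({"a": [1, 5], "b": [2, 2]}), category_count=4)
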