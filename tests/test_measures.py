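import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from qsarlab import (
    auc,
    binary_measures,
    build_performance_table,
    confusion,
    continuous_measures,
    initial_enhancement,
    threshold_scores,
)
from qsarlab.measures import ConfusionCounts


def brute_force_auc(y, scores):
    """Independent oracle: count positive-negative score pairs directly."""
    y = np.asarray(y)
    pos = np.asarray(scores)[y == 1]
    neg = np.asarray(scores)[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestThresholdScores:
    def test_ge_convention(self):
        np.testing.assert_array_equal(
            threshold_scores([0.2, 0.5, 0.9], 0.5), [0, 1, 1]
        )

    def test_minus_infinity_selects_all(self):
        np.testing.assert_array_equal(
            threshold_scores([0.1, -5.0], -np.inf), [1, 1]
        )

    def test_applies_to_unbounded_scores(self):
        np.testing.assert_array_equal(
            threshold_scores([-1.2, 3.4], 0.5), [0, 1]
        )


class TestConfusion:
    @pytest.mark.parametrize(
        "y, yhat, counts",
        [([1, 1, 0, 0], [1, 0, 0, 1], (1, 1, 1, 1)),
         ([1, 0, 1], [1, 0, 1], (2, 0, 1, 0)),
         ([1, 0], [0, 1], (0, 1, 0, 1))],
    )
    def test_enumeration(self, y, yhat, counts):
        c = confusion(y, yhat)
        assert (c.tp, c.fp, c.tn, c.fn) == counts
        assert c.n == len(y)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestBinaryMeasures:
    def test_symmetric_case(self):
        m = binary_measures(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert all(m[k] == pytest.approx(0.5) for k in m)

    def test_f1_harmonic_mean(self):
        # sens = 1/2, ppv = 1 -> f1 = 2 * 0.5 * 1 / 1.5 = 2/3
        m = binary_measures(ConfusionCounts(tp=1, fp=0, tn=2, fn=1))
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["ppv"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_zero_over_zero_marked_undefined(self):
        m = binary_measures(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert np.isnan(m["ppv"])
        assert np.isnan(m["f1"])

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.int8, st.integers(4, 40), elements=st.integers(0, 1)),
           st.randoms(use_true_random=False))
    def test_error_rate_complements_accuracy(self, y, rnd):
        yhat = np.array([rnd.randint(0, 1) for _ in y])
        c = confusion(y, yhat)
        m = binary_measures(c)
        assert m["error_rate"] == pytest.approx(1 - (c.tp + c.tn) / c.n)


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([1, 0], [0.9, 0.1]) == pytest.approx(1.0)

    def test_all_ties(self):
        assert auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_small_example_against_pair_counting(self):
        assert auc([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        y = np.zeros(n)
        y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        scores = rng.integers(0, 5, size=n).astype(float)  # force ties
        assert auc(y, scores) == pytest.approx(brute_force_auc(y, scores))

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_score_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(20) < 0.4).astype(float)
        if y.sum() in (0, 20):
            y[0] = 1 - y[0]
        s = rng.integers(0, 6, size=20).astype(float)
        assert auc(y, s) + auc(y, -s) == pytest.approx(1.0)


class TestInitialEnhancement:
    def test_perfect_ranking_at_m_equals_p(self):
        n, p = 100, 10
        y = np.r_[np.ones(p), np.zeros(n - p)]
        scores = -np.arange(n, dtype=float)  # descending: positives first
        assert initial_enhancement(y, scores, m=p) == pytest.approx(n / p)

    def test_hit_rate_equal_to_base_rate_gives_one(self):
        # n=100, p=10, m=10 containing exactly 1 positive
        y = np.zeros(100)
        y[[0, 20, 21, 22, 23, 24, 25, 26, 27, 28]] = 1
        scores = -np.arange(100, dtype=float)
        assert initial_enhancement(y, scores, m=10) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # n=100, p=10, m=20 with 6 positives in the top 20 -> IE = 3
        y = np.zeros(100)
        y[[0, 1, 2, 3, 4, 5, 50, 51, 52, 53]] = 1
        scores = -np.arange(100, dtype=float)
        assert initial_enhancement(y, scores, m=20) == pytest.approx(3.0)

    def test_m_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            initial_enhancement([1, 0], [0.5, 0.4], m=3)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_score_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(50) < 0.2).astype(float)
        if y.sum() == 0:
            y[0] = 1
        s = rng.standard_normal(50)
        base = initial_enhancement(y, s, m=10)
        assert initial_enhancement(y, np.exp(s), m=10) == pytest.approx(base)
        assert initial_enhancement(y, 3 * s + 7, m=10) == pytest.approx(base)


class TestContinuousMeasures:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = continuous_measures(y, y)
        assert m["rmse"] == pytest.approx(0.0)
        assert m["r2"] == pytest.approx(1.0)
        assert m["spearman"] == pytest.approx(1.0)

    def test_constant_prediction_at_mean_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        m = continuous_measures(y, np.full(3, 2.0))
        assert m["r2"] == pytest.approx(0.0)
        assert np.isnan(m["spearman"])  # constant yhat has no rank order

    def test_reversed_ranks(self):
        m = continuous_measures([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert m["spearman"] == pytest.approx(-1.0)

    def test_zero_variance_response_undefined(self):
        m = continuous_measures([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(m["r2"]) and np.isnan(m["spearman"])


class TestBuildPerformanceTable:
    def test_shape_and_blocking(self, small_store):
        table = build_performance_table(small_store, "auc")
        assert table.values.shape == (2, 6)  # 2 splits x (2 sets x 3 methods)
        assert table.larger_is_better

    def test_ie_uses_default_m_capped_at_n(self, small_store):
        table = build_performance_table(small_store, "ie")
        assert table.m == min(300, small_store.n)

    def test_incompatible_measure_lists_valid_ones(self, small_store):
        with pytest.raises(ValueError, match="rmse.*binary|continuous"):
            build_performance_table(small_store, "rmse")

    def test_unknown_measure(self, small_store):
        with pytest.raises(KeyError):
            build_performance_table(small_store, "mcc")

    def test_failed_combination_dropped_with_warning(self, small_store):
        import copy

        store = copy.deepcopy(small_store)
        del store.entries[(2, "BinarySet", "RF")]
        with pytest.warns(UserWarning, match="BinarySet/RF"):
            table = build_performance_table(store, "auc")
        assert "BinarySet/RF" not in table.values.columns
        assert table.values.shape == (2, 5)
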