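"""Unit oracles and invariants for the comparison-statistics suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shapcompare import (
    AttributionMatrix,
    compacity,
    consistency_std,
    correlation_between_methods,
    cumulative_present_absent,
    faithfulness,
    gini,
    holm_adjust,
    significance_tier,
    wilcoxon_holm,
)


def matrix(values, **kwargs):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    defaults = dict(
        base_values=np.zeros(n), fx=values.sum(1), method="test", model_label="m",
        trial_index=0, compound_ids=[f"c{i}" for i in range(n)],
        feature_ids=np.arange(m),
    )
    defaults.update(kwargs)
    return AttributionMatrix(values=values, **defaults)


class TestGini:
    def test_worked_example(self):
        assert gini([1, 2, 3, 4]) == pytest.approx(0.25)

    def test_equal_values_zero(self):
        assert gini([5, 5, 5]) == 0.0

    def test_zeros_removed_then_single_value(self):
        assert gini([0, 0, 0, 9]) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gini([1.0, -1.0])

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=20),
           st.floats(0.1, 10))
    def test_scale_invariance_and_range(self, values, scale):
        g = gini(values)
        assert 0.0 <= g < 1.0
        assert gini(np.array(values) * scale) == pytest.approx(g)

    def test_permutation_invariance(self):
        assert gini([4, 1, 3, 2]) == gini([1, 2, 3, 4])


class TestCompacity:
    def test_worked_example(self):
        assert compacity([0.5, 0.3, 0.1, 0.1], [0.7])[0] == 50.0

    def test_single_dominant_value(self):
        assert compacity([10.0, 1e-9, 1e-9, 1e-9, 1e-9], [0.5])[0] == 20.0  # 1/5

    def test_uniform_values(self):
        assert compacity([1.0] * 10, [0.9])[0] == 90.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=50)
        curve = compacity(values, np.linspace(0.05, 0.95, 19))
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] <= 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compacity([0.0, 0.0], [0.5])

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            compacity([1.0], [1.5])


class TestConsistencyStd:
    def test_identical_normalized_values_zero(self):
        # rows proportional: identical after normalization
        stds = consistency_std(np.array([[1.0, 3.0], [2.0, 6.0]]))
        assert np.allclose(stds, 0.0)

    def test_single_occurrence_missing(self):
        values = np.array([[1.0, 0.0], [1.0, 0.0]])
        stds = consistency_std(values)
        assert np.isnan(stds[1])

    def test_two_point_sample_std(self):
        # normalized values 0.1 and 0.3 for feature 1 -> sample std 0.1414
        values = np.array([[0.9, 0.1], [0.7, 0.3]])
        stds = consistency_std(values)
        assert stds[1] == pytest.approx(0.14142, abs=1e-4)

    def test_zero_rows_skipped(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 3.0]])
        stds = consistency_std(values)
        assert np.isfinite(stds).all()


class TestCorrelation:
    def test_proportional_matrices(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 5))
        assert correlation_between_methods(A, 2 * A) == pytest.approx(1.0)
        assert correlation_between_methods(A, -A) == pytest.approx(-1.0)
        assert correlation_between_methods(A, A) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(100, 100)), rng.normal(size=(100, 100))
        assert abs(correlation_between_methods(A, B)) < 0.05

    def test_subsets_use_bit_state(self):
        bits = np.array([[1, 0], [1, 0]])
        A = np.array([[1.0, 5.0], [2.0, 6.0]])
        B = np.array([[1.0, -5.0], [2.0, -6.0]])
        assert correlation_between_methods(A, B, bits, "present") == pytest.approx(1.0)
        assert correlation_between_methods(A, B, bits, "absent") == pytest.approx(-1.0)

    def test_zero_variance_missing(self):
        A = np.ones((3, 3))
        assert np.isnan(correlation_between_methods(A, A))

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            correlation_between_methods(np.ones((2, 2)), np.ones((3, 2)))


class TestFaithfulness:
    def linear(self, w):
        return lambda X: np.asarray(X) @ np.asarray(w, dtype=float)

    def test_additive_model_present_features(self):
        w = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, 0.0, 1.0, 1.0])
        # attribution = exact Shapley values for all-zeros background = w*x
        r = faithfulness(self.linear(w), x, w * x, "present")
        assert r == pytest.approx(1.0)

    def test_attribution_equal_to_marginals(self):
        w = np.array([0.5, -1.0, 2.0])
        x = np.array([1.0, 1.0, 0.0])
        f = self.linear(w)
        m = np.array([f(x[None])[0] - f(row[None])[0] for row in
                      [np.array([0., 1., 0.]), np.array([1., 0., 0.]),
                       np.array([1., 1., 1.])]])
        assert faithfulness(f, x, m, "all") == pytest.approx(1.0)

    def test_constant_attribution_missing(self):
        w = np.array([1.0, 2.0, 3.0])
        x = np.array([1.0, 1.0, 1.0])
        assert np.isnan(faithfulness(self.linear(w), x, np.ones(3), "present"))

    def test_small_subset_missing(self):
        w = np.array([1.0, 2.0])
        x = np.array([1.0, 0.0])
        assert np.isnan(faithfulness(self.linear(w), x, w, "present"))


class TestWilcoxonHolm:
    def test_holm_adjustment_worked_example(self):
        adjusted = holm_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adjusted, [0.03, 0.06, 0.06])

    def test_holm_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(size=12)
        adj = holm_adjust(raw)
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= 0)

    def test_tiers(self):
        assert significance_tier(2e-5) == "****"
        assert significance_tier(5e-4) == "***"
        assert significance_tier(5e-3) == "**"
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.2) == "ns"

    def test_identical_vectors_reported_missing(self):
        x = np.arange(10.0)
        df = wilcoxon_holm([("same", x, x), ("diff", x, x + 3.0)])
        assert df.loc[df.label == "same", "tier"].item() == "missing"
        assert np.isnan(df.loc[df.label == "same", "p_raw"].item())
        assert df.loc[df.label == "diff", "p_holm"].item() <= 0.05

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_holm([("x", [1, 2], [3, 4])])


class TestCumulativePresentAbsent:
    def test_worked_example(self):
        attr = matrix([[0.2, -0.1, 0.3]])
        bits = np.array([[1, 0, 1]])
        df = cumulative_present_absent(attr, bits, np.array([1]), np.array([1]))
        assert df.present_sum.item() == pytest.approx(0.5)
        assert df.absent_sum.item() == pytest.approx(-0.1)
        assert df.true_class.item() == "active"

    def test_incorrect_predictions_excluded(self):
        attr = matrix([[0.2, 0.1], [0.3, 0.4]])
        bits = np.ones((2, 2), dtype=int)
        df = cumulative_present_absent(attr, bits, np.array([1, 0]), np.array([1, 1]))
        assert len(df) == 1 and df.compound_id.item() == "c0"

    def test_zero_attribution_row(self):
        attr = matrix([[0.0, 0.0]])
        df = cumulative_present_absent(attr, np.array([[1, 0]]),
                                       np.array([0]), np.array([0]))
        assert df.present_sum.item() == 0.0
        assert np.isnan(df.present_sum_norm.item())

    def test_misaligned_rejected(self):
        attr = matrix([[0.1, 0.2]])
        with pytest.raises(ValueError):
            cumulative_present_absent(attr, np.ones((2, 2)), np.array([1, 0]),
                                      np.array([1, 0]))
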