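"""Trial design, Tanimoto kernel, training and the five performance metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shapcompare import (
    ModelSpec,
    PerformanceReport,
    SyntheticConfig,
    evaluate,
    generate_fingerprint_dataset,
    split_trials,
    tanimoto_kernel,
    tune_and_train,
)
from shapcompare.models import DEFAULT_GRIDS


class TestSplitTrials:
    def test_stratified_sizes(self):
        labels = np.array([1] * 100 + [0] * 100)
        splits = split_trials(labels, n_trials=10, seed=0)
        assert len(splits) == 10
        for s in splits:
            assert len(s.test_ids) == 20
            assert labels[s.test_ids].sum() == 10  # 10 actives per test set
            assert len(np.intersect1d(s.train_ids, s.test_ids)) == 0

    def test_determinism_and_shuffle_split_overlap(self):
        labels = np.array([1] * 100 + [0] * 100)
        a = split_trials(labels, n_trials=10, seed=5)
        b = split_trials(labels, n_trials=10, seed=5)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.test_ids, sb.test_ids)
        # independent shuffle-splits, not a K-fold partition: test sets repeat
        all_test = np.concatenate([s.test_ids for s in a])
        assert len(np.unique(all_test)) < len(all_test)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_trials(np.array([1, 0, 0, 0]), n_trials=2, seed=0)


class TestTanimotoKernel:
    def test_hand_counted_values(self):
        X = np.array([[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 0, 0]])
        K = tanimoto_kernel(X, X)
        assert K[0, 0] == 1.0                       # self-similarity
        assert K[1, 0] == pytest.approx(1 / 3)      # a=2, b=2, c=1
        assert K[1, 2] == 0.0                       # disjoint supports
        assert K[3, 3] == 1.0                       # 0/0 convention
        assert np.allclose(K, K.T)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_kernel(np.array([[0.5, 1.0]]), np.array([[1.0, 0.0]]))

    @given(st.integers(0, 2**6 - 1), st.integers(0, 2**6 - 1))
    def test_bounds_and_symmetry(self, a, b):
        x = np.array([(a >> i) & 1 for i in range(6)], dtype=float)[None]
        y = np.array([(b >> i) & 1 for i in range(6)], dtype=float)[None]
        k = tanimoto_kernel(x, y)[0, 0]
        assert 0.0 <= k <= 1.0
        assert k == tanimoto_kernel(y, x)[0, 0]


class TestPerformanceReport:
    def test_worked_counts(self):
        """TP=50 FP=10 TN=40 FN=0 plugged into the metric formulas."""
        r = PerformanceReport.from_counts(TP=50, FP=10, TN=40, FN=0)
        assert r.precision == pytest.approx(0.8333, abs=1e-4)
        assert r.recall == 1.0
        assert r.balanced_accuracy == pytest.approx(0.9)
        assert r.f1 == pytest.approx(0.9091, abs=1e-4)
        assert r.mcc == pytest.approx(0.8165, abs=1e-4)

    def test_perfect_and_inverted_predictions(self):
        perfect = PerformanceReport.from_counts(10, 0, 10, 0)
        assert (perfect.precision, perfect.recall, perfect.balanced_accuracy,
                perfect.f1, perfect.mcc) == (1.0, 1.0, 1.0, 1.0, 1.0)
        inverted = PerformanceReport.from_counts(0, 10, 0, 10)
        assert inverted.mcc == -1.0

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_metric_invariants(self, counts):
        tp, fp, tn, fn = counts
        r = PerformanceReport.from_counts(tp, fp, tn, fn)
        for v in (r.precision, r.recall, r.balanced_accuracy, r.f1):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= r.mcc <= 1.0
        # F1 is the harmonic mean of precision and recall
        if r.precision + r.recall > 0:
            assert r.f1 == pytest.approx(
                2 * r.precision * r.recall / (r.precision + r.recall)
            )
        # balanced test set: BA equals plain accuracy
        if tp + fn == tn + fp and tp + fn > 0:
            assert r.balanced_accuracy == pytest.approx(
                (tp + tn) / (tp + fp + tn + fn)
            )
        # MCC invariant to swapping classes together with predictions
        swapped = PerformanceReport.from_counts(tn, fn, tp, fp)
        assert r.mcc == pytest.approx(swapped.mcc)


class TestModelSpec:
    def test_default_grids_and_output_modes(self):
        assert ModelSpec("RFC").grid == DEFAULT_GRIDS["RFC"]
        assert ModelSpec("RFC").output_mode == "proba"
        assert ModelSpec("SVM_TAN").output_mode == "decision"
        assert ModelSpec("SVM_RBF").grid["C"][-1] == 10000

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("GBM")

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("SVM_RBF", grid={"C": [0, 1], "gamma": [0.1]})


def single_bit_dataset(n=60, seed=0):
    """Label equals bit 0 exactly: linearly separable by construction."""
    rng = np.random.default_rng(seed)
    bits = (rng.random((n, 8)) < 0.3).astype(np.uint8)
    labels = bits[:, 0].astype(np.int64)
    labels[: n // 2] = 1
    bits[: n // 2, 0] = 1
    labels[n // 2:] = 0
    bits[n // 2:, 0] = 0
    return bits.astype(float), labels


class TestTuneAndTrain:
    def test_separable_data_perfect_svm_tan(self):
        X, y = single_bit_dataset()
        split = split_trials(y, n_trials=1, seed=1)[0]
        model = tune_and_train(X, y, split, ModelSpec("SVM_TAN", grid={"C": [1, 10]}),
                               seed=0)
        rep = evaluate(model, X[split.test_ids], y[split.test_ids])
        assert rep.f1 == 1.0

    def test_selected_hyperparameters_deterministic(self):
        ds = generate_fingerprint_dataset(
            SyntheticConfig(seed=3, n_per_class=40, n_features=16, n_informative=4)
        )
        X, y = ds.X(), ds.labels
        split = split_trials(y, n_trials=1, seed=2)[0]
        spec = ModelSpec("RFC", grid={"min_samples_leaf": [1, 5],
                                      "min_samples_split": [2],
                                      "n_estimators": [25, 50]})
        a = tune_and_train(X, y, split, spec, seed=9)
        b = tune_and_train(X, y, split, spec, seed=9)
        assert a.params == b.params

    def test_no_signal_mcc_near_zero(self):
        cfg = SyntheticConfig(seed=8, n_per_class=40, n_features=32,
                              n_informative=0, p_on_background=0.2)
        ds = generate_fingerprint_dataset(cfg)
        X, y = ds.X(), ds.labels
        mccs = []
        for split in split_trials(y, n_trials=5, seed=0):
            model = tune_and_train(
                X, y, split,
                ModelSpec("RFC", grid={"min_samples_leaf": [1],
                                       "min_samples_split": [2],
                                       "n_estimators": [50]}),
                seed=split.trial_index,
            )
            mccs.append(evaluate(model, X[split.test_ids], y[split.test_ids]).mcc)
        assert abs(np.median(mccs)) < 0.5

    def test_degenerate_class_rejected(self):
        X = np.eye(4)
        y = np.array([1, 1, 1, 1])
        split = type("S", (), {"train_ids": np.arange(3), "test_ids": np.array([3]),
                               "trial_index": 0})()
        with pytest.raises(ValueError, match="degenerate"):
            tune_and_train(X, y, split, ModelSpec("RFC"), seed=0)

    def test_ffnn_trains_and_predicts_probabilities(self):
        X, y = single_bit_dataset(n=80, seed=4)
        split = split_trials(y, n_trials=1, seed=1)[0]
        model = tune_and_train(
            X, y, split, ModelSpec("FFNN", grid={"learning_rate_init": [0.01]}), seed=0
        )
        out = model.output(X[split.test_ids])
        assert np.all((out >= 0) & (out <= 1))
        assert evaluate(model, X[split.test_ids], y[split.test_ids]).mcc > 0.5

    def test_empty_test_set_rejected(self, trained_rfc, small_dataset):
        with pytest.raises(ValueError):
            evaluate(trained_rfc, small_dataset.X()[:0], small_dataset.labels[:0])
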