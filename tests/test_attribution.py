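"""Shapley axioms, value-function semantics and KernelSHAP equivalence."""

import numpy as np
import pytest

from shapcompare import (
    AttributionMatrix,
    MarginalValueFunction,
    additive_game,
    attribute_dataset,
    exact_shapley,
    kernel_shap,
    kernel_shap_game,
    make_toy_game,
    marginal_value_function,
    random_game,
    sample_background,
)
from shapcompare.attribution import _solve_constrained_wls, SingularDesignError


def linear_model(w):
    w = np.asarray(w, dtype=float)
    return lambda X: np.asarray(X, dtype=float) @ w


class TestExactShapley:
    def test_worked_two_player_game(self, worked_game):
        res = exact_shapley(worked_game)
        assert np.allclose(res.phi, [1.5, 2.5])
        assert res.base_value == 0.0 and res.fx == 4.0
        assert res.efficiency_gap < 1e-10

    def test_additivity_axiom(self):
        g = additive_game([1.0, -2.0, 0.5])
        assert np.allclose(exact_shapley(g).phi, [1.0, -2.0, 0.5])

    def test_dummy_axiom_constant_game(self):
        g = make_toy_game({S: 7.0 for S in
                           [(), (0,), (1,), (0, 1)]})
        assert np.allclose(exact_shapley(g).phi, 0.0)

    def test_symmetry_axiom(self):
        # v depends only on coalition size: all players symmetric
        sizes = {(): 0.0, (0,): 1.0, (1,): 1.0, (2,): 1.0,
                 (0, 1): 3.0, (0, 2): 3.0, (1, 2): 3.0, (0, 1, 2): 9.0}
        phi = exact_shapley(make_toy_game(sizes)).phi
        assert np.allclose(phi, phi[0])

    def test_efficiency_on_random_games(self):
        for seed in range(5):
            g = random_game(6, seed=seed)
            res = exact_shapley(g)
            assert abs(res.phi.sum() + res.base_value - res.fx) < 1e-10

    def test_enumeration_cap(self):
        class Fake:
            n_features = 17
            def values(self, Z):  # pragma: no cover
                return np.zeros(len(Z))
        with pytest.raises(ValueError, match="kernel_shap"):
            exact_shapley(Fake())


class TestMarginalValueFunction:
    def test_full_and_empty_coalitions(self, trained_rfc, small_dataset):
        X = small_dataset.X()
        bg = sample_background(trained_rfc.train_X, 20, seed=0)
        vf = marginal_value_function(trained_rfc, X[0], bg)
        full = vf.value(range(vf.n_features))
        assert full == pytest.approx(float(trained_rfc.output(X[:1])[0]))
        empty = vf.value(())
        assert empty == pytest.approx(float(trained_rfc.output(bg).mean()))

    def test_additive_model_zero_background(self):
        w = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, 0.0, 1.0, 1.0])
        vf = MarginalValueFunction(linear_model(w), x, np.zeros((1, 4)))
        assert vf.value((0,)) == pytest.approx(1.0)
        assert vf.value((0, 1)) == pytest.approx(1.0)   # bit 1 is off in x
        assert vf.value((2, 3)) == pytest.approx(7.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            MarginalValueFunction(lambda X: X.sum(1), np.zeros(3), np.zeros((2, 4)))

    def test_dummy_feature_exact_zero(self):
        # feature 1 constant across instance and background: phi exactly 0
        rng = np.random.default_rng(0)
        bg = rng.integers(0, 2, (8, 4)).astype(float)
        bg[:, 1] = 1.0
        x = np.array([1.0, 1.0, 0.0, 1.0])
        f = lambda X: X @ np.array([1.0, 5.0, -2.0, 0.5]) + (X[:, 1] * X[:, 3])
        vf = MarginalValueFunction(f, x, bg)
        assert exact_shapley(vf).phi[1] == 0.0


class TestKernelShap:
    def test_full_enumeration_matches_exact_on_games(self):
        for seed in (0, 1, 2):
            g = random_game(8, seed=seed)
            assert np.abs(kernel_shap_game(g).phi - exact_shapley(g).phi).max() < 1e-8

    def test_full_enumeration_matches_exact_on_model(self, trained_rfc, small_dataset):
        X = small_dataset.X()
        top8 = np.arange(8)
        bg = sample_background(trained_rfc.train_X[:, top8], 16, seed=1)
        vf = MarginalValueFunction(
            lambda rows: trained_rfc.output(
                np.hstack([rows, np.tile(X[0, 8:], (len(rows), 1))])
            ),
            X[0, top8], bg,
        )
        exact = exact_shapley(vf)
        kern = kernel_shap_game(vf)
        assert np.abs(exact.phi - kern.phi).max() < 1e-8

    def test_additive_model_recovered_from_sampled_coalitions(self):
        w = np.array([1.0, -2.0, 0.5, 3.0, 0.0, 1.5])
        g = additive_game(w)
        res = kernel_shap_game(g, n_samples=12, seed=0)
        assert np.abs(res.phi - w).max() < 1e-8

    def test_sampled_run_deterministic(self):
        g = random_game(9, seed=4)
        a = kernel_shap_game(g, n_samples=40, seed=7)
        b = kernel_shap_game(g, n_samples=40, seed=7)
        assert np.array_equal(a.phi, b.phi)

    def test_budget_below_minimum_rejected(self):
        g = random_game(8, seed=0)
        with pytest.raises(ValueError, match="n_samples"):
            kernel_shap_game(g, n_samples=10, seed=0)

    def test_rank_deficient_design_rejected(self):
        Z = np.array([[1.0, 0.0, 0.0]] * 4)  # one distinct coalition
        with pytest.raises(SingularDesignError):
            _solve_constrained_wls(Z, np.ones(4), np.ones(4), total=1.0)

    def test_efficiency_constraint_always_holds(self):
        g = random_game(10, seed=5)
        for ns in (20, 60, 200):
            res = kernel_shap_game(g, n_samples=ns, seed=1)
            assert abs(res.phi.sum() + res.base_value - res.fx) < 1e-8

    def test_convergence_with_budget(self):
        """Mean |error| vs exact decreases as the budget doubles (20 seeds)."""
        g = random_game(10, seed=12)
        exact = exact_shapley(g).phi
        maes = []
        for ns in (20, 40, 80, 160):
            errs = [
                np.abs(kernel_shap_game(g, n_samples=ns, seed=s).phi - exact).mean()
                for s in range(20)
            ]
            maes.append(np.mean(errs))
        assert all(a > b for a, b in zip(maes, maes[1:])), maes

    def test_model_convenience_wrapper(self, trained_rfc):
        bg = sample_background(trained_rfc.train_X, 10, seed=0)
        res = kernel_shap(trained_rfc, trained_rfc.train_X[0], bg,
                          n_samples=64, seed=0)
        assert res.phi.shape == (trained_rfc.n_features,)
        assert abs(res.phi.sum() + res.base_value - res.fx) < 1e-8


class TestAttributeDataset:
    def test_rows_satisfy_efficiency(self, trained_rfc, small_dataset):
        X = small_dataset.X()
        bg = sample_background(trained_rfc.train_X, 12, seed=0)
        attr = attribute_dataset(trained_rfc, X[:5], "kernel_shap", bg,
                                 n_samples=64, seed=3)
        assert attr.values.shape == (5, small_dataset.n_features)
        gaps = np.abs(attr.values.sum(1) + attr.base_values - attr.fx)
        assert gaps.max() < 1e-8

    def test_empty_rows_give_empty_matrix(self, trained_rfc):
        attr = attribute_dataset(trained_rfc, np.empty((0, trained_rfc.n_features)),
                                 "kernel_shap", np.zeros((1, trained_rfc.n_features)))
        assert attr.n_instances == 0

    def test_unknown_method_rejected(self, trained_rfc):
        with pytest.raises(ValueError, match="unknown attribution"):
            attribute_dataset(trained_rfc, trained_rfc.train_X[:1], "gradients")

    def test_csv_roundtrip(self, trained_rfc, small_dataset, tmp_path):
        X = small_dataset.X()
        bg = sample_background(trained_rfc.train_X, 8, seed=0)
        attr = attribute_dataset(trained_rfc, X[:3], "kernel_shap", bg,
                                 n_samples=48, seed=1,
                                 compound_ids=["a", "b", "c"], trial_index=2)
        path = tmp_path / "attr.csv"
        attr.to_csv(path)
        loaded = AttributionMatrix.from_csv(path)
        assert np.allclose(loaded.values, attr.values)
        assert loaded.trial_index == 2
        assert loaded.compound_ids == ["a", "b", "c"]
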