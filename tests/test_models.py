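import numpy as np
import pytest

from nicheforge import (ALGORITHMS, BioclimEnvelope, DomainGower, GlmNicheModel,
                        auc, make_model, predict_raster)

from conftest import make_stack


class TestBioclim:
    def test_median_scores_one(self):
        X = np.arange(1.0, 10.0).reshape(-1, 1)  # odd n, median 5
        m = BioclimEnvelope().fit(X)
        assert m.suitability([[5.0]])[0] == pytest.approx(1.0)

    def test_outside_training_range_scores_zero(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0)])
        m = BioclimEnvelope().fit(X)
        assert m.suitability([[100.0, 5.0]])[0] == 0.0
        assert m.suitability([[-1.0, 5.0]])[0] == 0.0

    def test_percentile_counting(self):
        # train {1..10}, query 3: p = (2 + 0.5)/10 = 0.25, score 0.5
        X = np.arange(1.0, 11.0).reshape(-1, 1)
        m = BioclimEnvelope().fit(X)
        assert m.suitability([[3.0]])[0] == pytest.approx(0.5)

    def test_invariant_to_variable_reordering(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        q = rng.normal(size=(10, 3))
        a = BioclimEnvelope().fit(X).suitability(q)
        b = BioclimEnvelope().fit(X[:, ::-1]).suitability(q[:, ::-1])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 2))
        q = rng.normal(size=(8, 2))
        base = BioclimEnvelope().fit(X).suitability(q)
        Xt = np.column_stack([np.exp(X[:, 0]), X[:, 1] ** 3])
        qt = np.column_stack([np.exp(q[:, 0]), q[:, 1] ** 3])
        np.testing.assert_allclose(BioclimEnvelope().fit(Xt).suitability(qt), base, atol=1e-12)

    def test_min_across_variables(self):
        X = np.column_stack([np.arange(1.0, 11.0), np.arange(1.0, 11.0)])
        m = BioclimEnvelope().fit(X)
        # var1 at median (score 1), var2 at 3 (score 0.5) -> min = 0.5
        assert m.suitability([[5.5, 3.0]])[0] == pytest.approx(0.5)


class TestDomain:
    def test_training_point_scores_one(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.3, 0.8]])
        m = DomainGower().fit(X)
        np.testing.assert_allclose(m.suitability(X), 1.0)

    def test_hand_computed_midpoint(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        m = DomainGower().fit(X)
        assert m.suitability([[0.5, 0.5]])[0] == pytest.approx(0.5)

    def test_clamped_at_zero(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        m = DomainGower().fit(X)
        assert m.suitability([[2.0, 2.0]])[0] == 0.0

    def test_zero_range_variable_convention(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])  # second variable constant
        m = DomainGower().fit(X)
        assert m.suitability([[1.0, 5.0]])[0] == pytest.approx(1.0)
        # differing on the constant variable costs a full term: d = (0 + 1)/2
        assert m.suitability([[1.0, 6.0]])[0] == pytest.approx(0.5)

    def test_invariant_to_variable_reordering(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        q = rng.normal(size=(7, 3))
        a = DomainGower().fit(X).suitability(q)
        b = DomainGower().fit(X[:, [2, 0, 1]]).suitability(q[:, [2, 0, 1]])
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestDiscriminative:
    def _toy(self, rng, sep=4.0, n=100):
        pres = rng.normal(loc=sep, size=(n, 2))
        back = rng.normal(loc=0.0, size=(n, 2))
        X = np.vstack([pres, back])
        y = np.array([1] * n + [0] * n)
        return X, y

    def test_glm_no_signal_predicts_prevalence(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = np.array([1, 0] * 100)
        m = GlmNicheModel().fit(X, y)
        p = m.suitability(rng.normal(size=(50, 2)))
        assert np.abs(p - 0.5).max() < 0.15

    def test_glm_monotone_in_positive_coefficient(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = (x + 0.3 * rng.normal(size=300) > 0).astype(int)
        m = GlmNicheModel().fit(x.reshape(-1, 1), y)
        assert m.model_.coef_[0, 0] > 0
        grid = np.linspace(-3, 3, 50).reshape(-1, 1)
        p = m.suitability(grid)
        assert np.all(np.diff(p) > 0)

    def test_glm_separable_data_perfect_test_auc(self):
        rng = np.random.default_rng(5)
        X, y = self._toy(rng, sep=10.0, n=50)
        m = GlmNicheModel().fit(X, y)
        Xt, yt = self._toy(rng, sep=10.0, n=30)
        s = m.suitability(Xt)
        assert auc(s[yt == 1], s[yt == 0]) == 1.0

    @pytest.mark.parametrize("algorithm", ["svm", "rf"])
    def test_separated_clusters_high_auc(self, algorithm):
        rng = np.random.default_rng(6)
        X, y = self._toy(rng, sep=4.0, n=100)
        m = make_model(algorithm, seed=0).fit(X, y)
        Xt, yt = self._toy(rng, sep=4.0, n=100)
        s = m.suitability(Xt)
        assert auc(s[yt == 1], s[yt == 0]) > 0.95

    @pytest.mark.parametrize("algorithm", ["svm", "rf"])
    def test_deterministic_given_seed(self, algorithm):
        rng = np.random.default_rng(7)
        X, y = self._toy(rng, n=50)
        q = rng.normal(size=(20, 2))
        a = make_model(algorithm, seed=123).fit(X, y).suitability(q)
        b = make_model(algorithm, seed=123).fit(X, y).suitability(q)
        np.testing.assert_array_equal(a, b)

    def test_rf_ambiguous_duplicated_points(self):
        # identical covariates with both labels: vote fraction near 0.5
        X = np.zeros((40, 2))
        y = np.array([1, 0] * 20)
        m = make_model("rf", seed=0, rf_trees=200).fit(X, y)
        assert abs(m.suitability([[0.0, 0.0]])[0] - 0.5) < 0.15

    def test_single_class_rejected(self):
        X = np.random.default_rng(8).normal(size=(10, 2))
        for alg in ("glm", "svm", "rf"):
            with pytest.raises(ValueError):
                make_model(alg).fit(X, np.ones(10, dtype=int))


class TestPredictRaster:
    def test_constant_stack_gives_point_prediction(self):
        stack = make_stack({"env1": np.full((3, 3), 2.0), "env2": np.full((3, 3), 7.0)})
        X = np.array([[1.0, 6.0], [3.0, 8.0]])
        m = DomainGower().fit(X)
        pred = predict_raster(m, stack, ["env1", "env2"])
        expected = m.suitability([[2.0, 7.0]])[0]
        np.testing.assert_allclose(pred.values, expected)

    def test_domain_training_presence_cell_is_one(self):
        rng = np.random.default_rng(9)
        stack = make_stack({"env1": rng.normal(size=(4, 4))})
        cell = stack.grid.flat_index(1, 2)
        X = stack.values_at_cells(np.array([cell, 0]), ["env1"])
        m = DomainGower().fit(X)
        pred = predict_raster(m, stack, ["env1"])
        assert pred.values[1, 2] == pytest.approx(1.0)

    def test_nodata_propagates(self):
        arr = np.random.default_rng(10).normal(size=(3, 3))
        arr[0, 0] = np.nan
        stack = make_stack({"env1": arr})
        m = BioclimEnvelope().fit(np.array([[0.0], [1.0], [2.0]]))
        pred = predict_raster(m, stack, ["env1"])
        assert np.isnan(pred.values[0, 0])
        assert np.isfinite(pred.values[1:]).all()

    def test_locality_outside_mask_irrelevant(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(size=(4, 4))
        arr2 = arr.copy()
        arr[0, 0] = np.nan
        arr2[0, 0] = np.nan
        stack_a = make_stack({"env1": arr})
        arr2_mod = arr2.copy()
        stack_b = make_stack({"env1": arr2_mod})
        m = BioclimEnvelope().fit(rng.normal(size=(10, 1)))
        a = predict_raster(m, stack_a, ["env1"]).values
        b = predict_raster(m, stack_b, ["env1"]).values
        np.testing.assert_array_equal(a[~np.isnan(a)], b[~np.isnan(b)])

    def test_svm_raster_is_range_normalized(self):
        rng = np.random.default_rng(12)
        stack = make_stack({"env1": rng.normal(size=(6, 6)),
                            "env2": rng.normal(size=(6, 6))})
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        m = make_model("svm", seed=0).fit(X, y)
        pred = predict_raster(m, stack, ["env1", "env2"])
        assert np.nanmin(pred.values) == pytest.approx(0.0)
        assert np.nanmax(pred.values) == pytest.approx(1.0)


def test_all_algorithms_constructible():
    for alg in ALGORITHMS:
        assert make_model(alg) is not None
    with pytest.raises(ValueError):
        make_model("maxent")
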