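import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from dtiforest import (
    ChiSquareWeights,
    FeatureWeightedRotationForest,
    chi2_weights,
    discretize,
    select_features,
)
from conftest import planted_dataset


def chi2_bruteforce(column, y):
    """Independent oracle: enumerate value/class cells with plain dicts."""
    n = len(y)
    values, classes = sorted(set(column)), sorted(set(y))
    total = 0.0
    for v in values:
        for c in classes:
            obs = sum(1 for f, lab in zip(column, y) if f == v and lab == c)
            exp = (sum(1 for f in column if f == v)
                   * sum(1 for lab in y if lab == c)) / n
            if exp > 0:
                total += (obs - exp) ** 2 / exp
    return total


class TestDiscretize:
    def test_binary_column_passes_through(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        codes, edges = discretize(X, n_bins=5)
        np.testing.assert_array_equal(codes[:, 0], [0, 1, 0, 1])
        assert edges[0] is None

    def test_equal_frequency_bins(self):
        X = np.arange(10.0)[:, None]
        codes, _ = discretize(X, n_bins=5)
        counts = np.bincount(codes[:, 0])
        assert counts.size == 5 and (counts == 2).all()

    def test_constant_column_single_category(self):
        X = np.full((8, 1), 3.3)
        codes, _ = discretize(X, n_bins=5)
        assert np.unique(codes[:, 0]).size == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            discretize(np.zeros((3, 1)), n_bins=1)


class TestChi2Weights:
    def test_feature_identical_to_class_on_balanced_sample(self):
        # 2x2 table with all-diagonal mass: each cell contributes (10-5)^2/5
        y = np.array([0] * 10 + [1] * 10)
        Xcat = y[:, None].copy()
        w = chi2_weights(Xcat, y)
        assert w.weights[0] == pytest.approx(20.0, abs=1e-12)

    def test_independent_feature_scores_zero(self):
        y = np.array([0, 0, 1, 1] * 5)
        Xcat = np.array([0, 1, 0, 1] * 5)[:, None]
        w = chi2_weights(Xcat, y)
        assert w.weights[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Xcat = rng.integers(0, 4, size=(30, 5))
        y = rng.integers(0, 2, size=30)
        if np.unique(y).size < 2:
            y[0] = 1 - y[0]
        w = chi2_weights(Xcat, y)
        for j in range(5):
            expected = chi2_bruteforce(list(Xcat[:, j]), list(y))
            assert w.weights[j] == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(99)
        col = rng.integers(0, 3, size=40)
        y = rng.integers(0, 2, size=40)
        w = chi2_weights(col[:, None], y)
        table = np.zeros((3, 2))
        for v, c in zip(col, y):
            table[v, c] += 1
        table = table[table.sum(axis=1) > 0]
        stat, *_ = chi2_contingency(table, correction=False)
        assert w.weights[0] == pytest.approx(stat, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            chi2_weights(np.zeros((4, 1), dtype=int), np.zeros(4, dtype=int))


class TestSelectFeatures:
    def make(self, weights):
        return ChiSquareWeights(np.asarray(weights, float), [None] * len(weights))

    def test_keep_all(self):
        np.testing.assert_array_equal(
            select_features(self.make([1, 2, 3]), 1.0), [0, 1, 2]
        )

    def test_descending_order_selection(self):
        np.testing.assert_array_equal(
            select_features(self.make([3, 1, 2]), 2 / 3), [0, 2]
        )

    def test_tie_breaks_to_lower_index(self):
        np.testing.assert_array_equal(
            select_features(self.make([2, 2, 1]), 1 / 3), [0]
        )

    @pytest.mark.parametrize("frac", [0.0, 1.5, -0.2])
    def test_fraction_bounds(self, frac):
        with pytest.raises(ValueError, match="keep_fraction"):
            select_features(self.make([1, 2]), frac)


class TestRotationForestFit:
    def test_rotations_are_orthonormal_block_diagonal(self):
        X, y = planted_dataset(n_samples=60, n_features=4, n_informative=2, seed=1)
        model = FeatureWeightedRotationForest(
            n_subsets=2, n_trees=3, seed=0
        ).fit(X, y)
        for R, partition in zip(model.rotations_, model.partitions_):
            assert R.shape == (4, 4)
            np.testing.assert_allclose(R.T @ R, np.eye(4), atol=1e-8)
            # off-block entries must be exactly zero
            for idx in partition:
                other = np.setdiff1d(np.arange(4), idx)
                assert np.all(R[np.ix_(idx, other)] == 0)
            sizes = sorted(len(idx) for idx in partition)
            assert sizes[-1] - sizes[0] <= 1

    def test_partition_covers_features_exactly_once(self):
        X, y = planted_dataset(n_samples=80, n_features=13, seed=2)
        model = FeatureWeightedRotationForest(n_subsets=4, n_trees=2, seed=3).fit(X, y)
        for partition in model.partitions_:
            flat = np.concatenate(partition)
            np.testing.assert_array_equal(np.sort(flat), np.arange(13))

    def test_too_many_subsets_rejected(self):
        X, y = planted_dataset(n_samples=40, n_features=4, n_informative=2, seed=4)
        with pytest.raises(ValueError, match="n_subsets"):
            FeatureWeightedRotationForest(n_subsets=5).fit(X, y)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            FeatureWeightedRotationForest(n_subsets=2).fit(X, np.zeros(10, int))

    @pytest.mark.parametrize("r", [0.0, 1.2])
    def test_bootstrap_fraction_bounds(self, r):
        X, y = planted_dataset(n_samples=40, n_features=4, n_informative=2, seed=5)
        with pytest.raises(ValueError, match="bootstrap_fraction"):
            FeatureWeightedRotationForest(n_subsets=2, bootstrap_fraction=r).fit(X, y)

    def test_chi2_keep_reduces_feature_count(self):
        X, y = planted_dataset(n_samples=100, n_features=20, seed=6)
        model = FeatureWeightedRotationForest(
            n_subsets=2, n_trees=2, chi2_keep=0.5, seed=0
        ).fit(X, y)
        assert model.retained_.size == 10
        np.testing.assert_array_equal(model.retained_, np.sort(model.retained_))


class TestPredict:
    def fitted(self, seed=0):
        X, y = planted_dataset(n_samples=120, n_features=12, seed=7)
        model = FeatureWeightedRotationForest(n_subsets=3, n_trees=5, seed=seed)
        return model.fit(X, y), X

    def test_confidence_rows_sum_to_one(self):
        model, X = self.fitted()
        conf = model.predict_confidence(X)
        np.testing.assert_allclose(conf.sum(axis=1), 1.0, atol=1e-12)
        assert (conf >= 0).all()

    def test_single_tree_confidence_equals_tree_distribution(self):
        X, y = planted_dataset(n_samples=80, n_features=8, seed=8)
        model = FeatureWeightedRotationForest(n_subsets=2, n_trees=1, seed=0).fit(X, y)
        conf = model.predict_confidence(X)
        tree_proba = model.trees_[0].predict_proba(
            X[:, model.retained_] @ model.rotations_[0]
        )
        np.testing.assert_allclose(conf, tree_proba)

    def test_predict_is_argmax_of_confidence(self):
        model, X = self.fitted()
        conf = model.predict_confidence(X)
        np.testing.assert_array_equal(model.predict(X), conf[:, 1] > conf[:, 0])

    def test_exact_tie_resolves_to_class_zero(self, monkeypatch):
        model, X = self.fitted()
        monkeypatch.setattr(
            model, "predict_confidence",
            lambda X: np.array([[0.5, 0.5], [0.2, 0.8]]),
        )
        np.testing.assert_array_equal(model.predict(X[:2]), [0, 1])

    def test_width_mismatch_rejected(self):
        model, X = self.fitted()
        with pytest.raises(ValueError, match="columns"):
            model.predict(X[:, :5])

    def test_seed_determinism(self):
        X, y = planted_dataset(n_samples=120, n_features=12, seed=9)
        grid = np.random.default_rng(1).standard_normal((30, 12))
        a = FeatureWeightedRotationForest(n_subsets=3, n_trees=4, seed=11).fit(X, y)
        b = FeatureWeightedRotationForest(n_subsets=3, n_trees=4, seed=11).fit(X, y)
        np.testing.assert_array_equal(
            a.predict_confidence(grid), b.predict_confidence(grid)
        )

    def test_save_load_reproduces_predictions(self, tmp_path):
        model, X = self.fitted()
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = FeatureWeightedRotationForest.load(path)
        np.testing.assert_array_equal(
            model.predict_confidence(X), loaded.predict_confidence(X)
        )


class TestEnsembleStability:
    def test_fold_auc_variance_shrinks_with_ensemble_size(self):
        """Averaged over seeds, a 21-tree ensemble has (weakly) less
        fold-to-fold AUC variance than a single rotated tree."""
        from dtiforest import cross_validate

        var1, var21 = [], []
        for seed in range(10):
            X, y = planted_dataset(n_samples=150, n_features=30,
                                   n_informative=6, seed=seed)
            for n_trees, sink in ((1, var1), (21, var21)):
                rep = cross_validate(
                    X, y, folds=5,
                    params={"n_subsets": 5, "n_trees": n_trees}, seed=seed,
                )
                aucs = [m.auc for m in rep.per_fold]
                sink.append(np.var(aucs))
        assert np.mean(var21) <= np.mean(var1)
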