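"""Gini impurity, pixel datasets, forest fitting and majority voting."""

import numpy as np
import pytest

import sporeseg as ss
from sporeseg.cnn_features import FeatureStack
from sporeseg.forest import majority_vote


class TestGini:
    @pytest.mark.parametrize(
        "p,expected",
        [([1.0, 0.0], 0.0), ([0.5, 0.5], 0.5), ([1 / 8] * 8, 0.875)],
    )
    def test_reference_values(self, p, expected):
        assert ss.gini_impurity(p) == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_loop(self, rng):
        """Oracle equivalence on 1000 random distributions."""
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            p = rng.random(n)
            p /= p.sum()
            brute = 1.0 - sum(float(pi) * float(pi) for pi in p)
            assert ss.gini_impurity(p) == pytest.approx(brute, abs=1e-12)

    def test_bounds_and_purity(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            p = rng.dirichlet(np.ones(n))
            g = ss.gini_impurity(p)
            assert 0.0 <= g <= 1.0 - 1.0 / n + 1e-12

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            ss.gini_impurity([0.5, 0.4])


def _toy_stack(labels_grid, rng, n_channels=6):
    """Features where channel 0 linearly separates the classes."""
    hb, wb = labels_grid.shape
    values = rng.random((hb, wb, n_channels)).astype(np.float32) * 0.1
    values[:, :, 0] = labels_grid  # perfectly informative channel
    return FeatureStack(values=values, image_id="toy")


class TestPixelDataset:
    def test_fully_labeled_grid_gives_all_cells(self, rng):
        grid = rng.integers(1, 9, (32, 26)).astype(np.uint8)
        stack = _toy_stack(grid, rng)
        data = ss.build_pixel_dataset(
            [stack], [grid], ss.RFConfig(max_pixels_per_image=None)
        )
        assert len(data) == 832

    def test_zero_cells_excluded(self, rng):
        grid = rng.integers(1, 9, (10, 10)).astype(np.uint8)
        grid.ravel()[:10] = 0
        data = ss.build_pixel_dataset(
            [_toy_stack(grid, rng)], [grid], ss.RFConfig(max_pixels_per_image=None)
        )
        assert len(data) == 90
        assert (data.labels > 0).all()

    def test_per_image_cap(self, rng):
        grids = [rng.integers(1, 9, (10, 10)).astype(np.uint8) for _ in range(3)]
        stacks = [_toy_stack(g, rng) for g in grids]
        data = ss.build_pixel_dataset(stacks, grids, ss.RFConfig(max_pixels_per_image=33))
        assert len(data) == 99

    def test_dim_mismatch_rejected(self, rng):
        grid = rng.integers(1, 9, (10, 10)).astype(np.uint8)
        with pytest.raises(ValueError):
            ss.build_pixel_dataset([_toy_stack(grid, rng)], [grid[:5]], ss.RFConfig())


def _separable_dataset(rng, n=120, n_channels=6):
    labels = rng.choice([2, 3, 8], size=n)
    feats = rng.random((n, n_channels)).astype(np.float32) * 0.1
    feats[:, 0] = labels * 10.0  # widely separated clusters
    return ss.PixelDataset(features=feats, labels=labels)


class TestForestFit:
    def test_separable_data_memorized(self, rng):
        data = _separable_dataset(rng)
        forest = ss.fit_random_forest(data, ss.RFConfig(n_trees=20, features_per_split=3))
        pred, _ = ss.rf_predict(forest, data.features)
        assert (pred == data.labels).all()

    def test_seeded_determinism(self, rng):
        data = _separable_dataset(rng)
        cfg = ss.RFConfig(n_trees=15, features_per_split=3, seed=4)
        probe = rng.random((40, data.features.shape[1])).astype(np.float32)
        a, _ = ss.rf_predict(ss.fit_random_forest(data, cfg), probe)
        b, _ = ss.rf_predict(ss.fit_random_forest(data, cfg), probe)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self, rng):
        data = ss.PixelDataset(
            features=rng.random((20, 4)).astype(np.float32),
            labels=np.full(20, 3),
        )
        with pytest.raises(ValueError):
            ss.fit_random_forest(data)

    def test_empty_rejected(self):
        data = ss.PixelDataset(
            features=np.empty((0, 4), dtype=np.float32), labels=np.empty(0, dtype=int)
        )
        with pytest.raises(ValueError):
            ss.fit_random_forest(data)


class TestVoting:
    def test_votes_sum_to_tree_count(self, rng):
        data = _separable_dataset(rng)
        forest = ss.fit_random_forest(data, ss.RFConfig(n_trees=17, features_per_split=3))
        _, votes = ss.rf_predict(forest, rng.random((30, 6)).astype(np.float32))
        assert (votes.sum(axis=1) == 17).all()

    def test_unanimity(self, rng):
        data = _separable_dataset(rng)
        # all features considered per split, so every tree splits on channel 0
        forest = ss.fit_random_forest(data, ss.RFConfig(n_trees=25, features_per_split=6))
        probe = np.full((1, 6), 0.05, dtype=np.float32)  # noise dims mid-range
        probe[0, 0] = 30.0  # deep inside class 3 territory
        labels, votes = ss.rf_predict(forest, probe)
        assert labels[0] == 3
        assert votes[0, 2] == 25

    def test_tie_breaks_to_lowest_class(self):
        votes = np.zeros((1, 8), dtype=int)
        votes[0, 1] = 150  # class 2
        votes[0, 5] = 150  # class 6
        assert majority_vote(votes)[0] == 2

    def test_single_tree_forest_matches_its_tree(self, rng):
        data = _separable_dataset(rng)
        forest = ss.fit_random_forest(data, ss.RFConfig(n_trees=1, features_per_split=3))
        probe = rng.random((25, 6)).astype(np.float32)
        labels, _ = ss.rf_predict(forest, probe)
        est = forest.sklearn_model.estimators_[0]
        tree_labels = forest.sklearn_model.classes_[est.predict(probe).astype(int)]
        assert np.array_equal(labels, tree_labels.astype(labels.dtype))

    def test_width_mismatch_rejected(self, rng):
        data = _separable_dataset(rng)
        forest = ss.fit_random_forest(data, ss.RFConfig(n_trees=3, features_per_split=3))
        with pytest.raises(ValueError):
            ss.rf_predict(forest, rng.random((5, 7)).astype(np.float32))

    def test_growing_the_forest_keeps_unanimous_predictions(self, rng):
        """Monotone stability: extra trees cannot flip a unanimous vote here."""
        data = _separable_dataset(rng)
        probe = rng.random((50, 6)).astype(np.float32) * 0.1
        probe[:, 0] = rng.choice([2, 3, 8], size=50) * 10.0
        small = ss.fit_random_forest(data, ss.RFConfig(n_trees=20, features_per_split=3, seed=7))
        big = ss.fit_random_forest(data, ss.RFConfig(n_trees=60, features_per_split=3, seed=7))
        labels_s, votes_s = ss.rf_predict(small, probe)
        labels_b, _ = ss.rf_predict(big, probe)
        unanimous = votes_s.max(axis=1) == 20
        assert unanimous.any()
        assert np.array_equal(labels_s[unanimous], labels_b[unanimous])


class TestSegmentationMap:
    def test_label_vote_consistency_enforced(self):
        votes = np.zeros((2, 2, 8), dtype=int)
        votes[..., 2] = 5
        labels = np.full((2, 2), 3)
        segmap = ss.SegmentationMap(labels=labels, votes=votes)
        assert segmap.shape == (2, 2)
        with pytest.raises(ValueError):
            ss.SegmentationMap(labels=np.full((2, 2), 4), votes=votes)

    def test_rejects_out_of_range_labels(self):
        votes = np.zeros((1, 1, 8), dtype=int)
        with pytest.raises(ValueError):
            ss.SegmentationMap(labels=np.array([[9]]), votes=votes)
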