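"""SVM panel search, LOOCV mechanics and hierarchical clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from medeg import (
    SvmConfig,
    cluster_misclassification,
    hierarchical_cluster,
    loocv_svm,
    search_feature_panel,
)
from medeg.exceptions import ValidationError
from medeg.panel import _loocv_folds

SMALL_GRID = SvmConfig(cost_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1))
ONE_POINT = SvmConfig(cost_grid=(1.0,), gamma_grid=(0.1,))


def separable_data(seed=0, n_a=10, n_b=10, gap=10.0, n_noise=2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_a + n_b, 1 + n_noise))
    x[n_a:, 0] += gap
    y = np.array(["a"] * n_a + ["b"] * n_b)
    cols = [f"f{j}" for j in range(1 + n_noise)]
    return pd.DataFrame(x, columns=cols), y


class TestLoocv:
    def test_separable_perfect_accuracy(self):
        feats, y = separable_data()
        res = loocv_svm(feats, y, SMALL_GRID)
        assert res.loocv_accuracy == 1.0
        assert len(res.per_sample_predictions) == len(y)

    def test_shuffled_labels_near_chance(self):
        # labels permuted independently of the features: LOOCV accuracy
        # stays near chance, never systematically high or low
        rng = np.random.default_rng(12)
        x = pd.DataFrame(rng.normal(size=(37, 3)))
        x.columns = [f"f{j}" for j in range(3)]
        y = np.array(["a"] * 19 + ["b"] * 18)
        cfg = SvmConfig(cost_grid=(10.0,), gamma_grid=(1.0,))
        shuffler = np.random.default_rng(999)
        inside = 0
        n_rep = 100
        for _ in range(n_rep):
            ys = shuffler.permutation(y)
            acc = loocv_svm(x, ys, cfg).loocv_accuracy
            inside += 0.25 <= acc <= 0.75
        assert inside / n_rep >= 0.95

    def test_single_class_rejected(self):
        feats, _ = separable_data()
        with pytest.raises(ValidationError):
            loocv_svm(feats, np.array(["a"] * len(feats)), ONE_POINT)

    def test_tie_prefers_smallest_cost_then_gamma(self):
        feats, y = separable_data(gap=50.0)
        cfg = SvmConfig(cost_grid=(8.0, 0.5), gamma_grid=(0.2, 0.05))
        res = loocv_svm(feats, y, cfg)
        # strongly separable: every grid point is perfect, so the
        # smallest cost and gamma must win
        assert res.loocv_accuracy == 1.0
        assert res.chosen_cost == 0.5
        assert res.chosen_gamma == 0.05

    def test_fold_scaler_ignores_held_out_sample(self):
        feats, y = separable_data(seed=5)
        x = feats.to_numpy()
        folds_a = _loocv_folds(x)
        x2 = x.copy()
        x2[3] += 1e6  # wildly corrupt one sample
        folds_b = _loocv_folds(x2)
        # training-fold geometry of the corrupted sample's own fold is
        # untouched: its statistics never leaked into the scaler
        np.testing.assert_allclose(folds_a[3][0], folds_b[3][0])

    def test_constant_feature_never_changes_predictions(self):
        feats, y = separable_data(seed=6)
        res1 = loocv_svm(feats, y, SMALL_GRID)
        feats2 = feats.copy()
        feats2["const"] = 7.7
        res2 = loocv_svm(feats2, y, SMALL_GRID)
        assert res1.loocv_accuracy == res2.loocv_accuracy
        assert (
            res1.per_sample_predictions == res2.per_sample_predictions
        ).all()


class TestPanelSearch:
    def test_informative_panel_found(self):
        rng = np.random.default_rng(7)
        n_a, n_b = 10, 10
        x = rng.normal(size=(n_a + n_b, 8))
        x[n_b:, :3] += 3.0  # three informative features among eight
        cols = [f"g{j}" for j in range(8)]
        feats = pd.DataFrame(x, columns=cols)
        y = np.array(["a"] * n_a + ["b"] * n_b)
        res = search_feature_panel(feats, y, SMALL_GRID, max_size=3, mode="greedy")
        assert res.loocv_accuracy == 1.0
        assert set(res.feature_ids) <= {"g0", "g1", "g2"}

    def test_single_candidate(self):
        feats, y = separable_data(n_noise=0)
        res = search_feature_panel(feats, y, ONE_POINT, max_size=1)
        assert res.feature_ids == ["f0"]

    def test_all_noise_warns(self):
        rng = np.random.default_rng(8)
        feats = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        y = np.array(["x"] * 10 + ["y"] * 10)
        with pytest.warns(UserWarning, match="majority"):
            search_feature_panel(feats, y, ONE_POINT, max_size=2)

    def test_greedy_matches_exhaustive_on_separable(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(16, 5))
        x[8:, 0] += 6.0
        feats = pd.DataFrame(x, columns=[f"g{j}" for j in range(5)])
        y = np.array(["a"] * 8 + ["b"] * 8)
        greedy = search_feature_panel(feats, y, ONE_POINT, max_size=2, mode="greedy")
        exhaust = search_feature_panel(
            feats, y, ONE_POINT, max_size=2, mode="exhaustive"
        )
        assert greedy.loocv_accuracy == exhaust.loocv_accuracy == 1.0

    def test_exhaustive_per_size_is_best_subset(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(14, 4))
        x[7:, 1] += 4.0
        feats = pd.DataFrame(x, columns=["a", "b", "c", "d"])
        y = np.array(["u"] * 7 + ["v"] * 7)
        res = search_feature_panel(feats, y, ONE_POINT, max_size=2, mode="exhaustive")
        best1 = res.per_size[1]
        accs = {
            c: loocv_svm(feats[[c]], y, ONE_POINT).loocv_accuracy
            for c in feats.columns
        }
        assert best1.loocv_accuracy == max(accs.values())

    def test_max_size_validated(self):
        feats, y = separable_data(n_noise=0)
        with pytest.raises(ValidationError):
            search_feature_panel(feats, y, ONE_POINT, max_size=5)


def average_linkage_oracle(points):
    """Brute-force average-linkage merge heights for a few points."""
    clusters = {i: [i] for i in range(len(points))}
    d = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points))
        for j in range(i + 1, len(points))
    }

    def cdist(a, b):
        return np.mean(
            [d[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]]
        )

    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((cdist(a, b), a, b) for a, b in itertools.combinations(keys, 2))
        )
        h, a, b = best
        heights.append(h)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestClustering:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.1, size=(5, 6))
        b = rng.normal(5, 0.1, size=(5, 6))
        m = pd.DataFrame(
            np.vstack([a, b]).T, columns=[f"s{i}" for i in range(10)]
        )
        _, assign = hierarchical_cluster(m, distance="euclidean")
        truth = pd.Series(["a"] * 5 + ["b"] * 5, index=m.columns)
        assert cluster_misclassification(assign, truth) == 0

    def test_merge_heights_match_enumeration(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(6, 3))
        m = pd.DataFrame(pts.T, columns=[f"s{i}" for i in range(6)])
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        z = linkage(pdist(pts), method="average")
        assert np.allclose(sorted(z[:, 2]), sorted(average_linkage_oracle(pts)))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(
            rng.normal(size=(8, 7)), columns=[f"s{i}" for i in range(7)]
        )
        _, assign1 = hierarchical_cluster(m)
        perm = rng.permutation(7)
        _, assign2 = hierarchical_cluster(m.iloc[:, perm])
        # same partition up to cluster relabeling
        a1 = assign1.loc[assign2.index]
        same = (a1 == assign2).all() or (a1 == 3 - assign2).all()
        assert same

    def test_constant_matrix_correlation_rejected(self):
        m = pd.DataFrame(np.ones((4, 5)), columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            hierarchical_cluster(m, distance="correlation")


class TestMisclassification:
    def setup_method(self):
        self.truth = pd.Series(
            ["case"] * 4 + ["control"] * 4, index=[f"s{i}" for i in range(8)]
        )

    def test_perfect_separation(self):
        assign = pd.Series([1] * 4 + [2] * 4, index=self.truth.index)
        assert cluster_misclassification(assign, self.truth) == 0

    def test_one_crossed_sample(self):
        assign = pd.Series([1, 1, 1, 2, 2, 2, 2, 2], index=self.truth.index)
        assert cluster_misclassification(assign, self.truth) == 1

    def test_relabeling_symmetry(self):
        assign = pd.Series([1, 1, 1, 2, 2, 2, 2, 2], index=self.truth.index)
        flipped = 3 - assign
        assert cluster_misclassification(
            assign, self.truth
        ) == cluster_misclassification(flipped, self.truth)
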