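"""Jaccard KNN, cross-validation, subset search, and correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexsig import ml
from flexsig.features import FEATURE_NAMES, FeatureMatrix
from flexsig.rigidity import AnalysisConfig
from flexsig.synthetic import FeatureGenSpec, make_feature_dataset


class TestJaccard:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0, 1), (1, 0, 1), 1.0),
        ((1, 0, 1), (1, 0, 0), 0.5),
        ((0, 0, 0), (0, 0, 0), 1.0),   # all-zero convention
        ((1, 1, 0), (0, 0, 1), 0.0),
    ])
    def test_values(self, u, v, expected):
        assert ml.jaccard_similarity(u, v) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ml.jaccard_similarity((1, 0), (1, 0, 1))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=20),
           st.data())
    def test_symmetry_and_bounds(self, u, data):
        v = data.draw(st.lists(st.booleans(), min_size=len(u),
                               max_size=len(u)))
        s = ml.jaccard_similarity(u, v)
        assert 0.0 <= s <= 1.0
        assert s == ml.jaccard_similarity(v, u)
        assert ml.jaccard_similarity(u, u) == 1.0


class TestKnnPredict:
    train = np.array([[1, 0, 0]] * 3 + [[1, 0, 1]] * 2 + [[0, 1, 1]])
    labels = np.array([0, 0, 0, 1, 1, 1])

    def test_worked_three_feature_example(self):
        """Two exact-match actives at similarity 1.0 outvote the nearest
        inactive at 0.5."""
        assert ml.knn_predict(self.train, self.labels, (1, 0, 1), k=3) == 1

    def test_exact_match_k1(self):
        assert ml.knn_predict(self.train, self.labels, (0, 1, 1), k=1) == 1
        assert ml.knn_predict(self.train, self.labels, (1, 0, 0), k=1) == 0

    def test_single_class_training(self):
        assert ml.knn_predict(self.train[:3], np.zeros(3, int),
                              (0, 1, 1), k=3) == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ml.knn_predict(self.train, self.labels, (1, 0, 1), k=2)

    def test_k_larger_than_training_rejected(self):
        with pytest.raises(ValueError):
            ml.knn_predict(self.train, self.labels, (1, 0, 1), k=7)


def _separating_matrix(n_active=9, n_inactive=18):
    """One feature that equals the activity label exactly, others zero."""
    data = np.zeros((n_active + n_inactive, len(FEATURE_NAMES)), dtype=np.int8)
    labels = np.array([0] * n_inactive + [1] * n_active, dtype=np.int8)
    data[:, FEATURE_NAMES.index("H2.2s")] = labels
    data[:, FEATURE_NAMES.index("H1.1l")] = 1  # shared background bit
    ids = [f"s{i}" for i in range(n_active + n_inactive)]
    return FeatureMatrix(ids, data, labels)


class TestLOOCV:
    def test_perfect_separator_scores_100(self):
        m = _separating_matrix()
        assert ml.loocv_accuracy(m, ["H2.2s", "H1.1l"], k=3) == 100.0

    def test_matches_reference_implementation(self, planted_matrix):
        rng = np.random.default_rng(1)
        for _ in range(10):
            sub = list(rng.choice(FEATURE_NAMES,
                                  size=rng.integers(1, 9), replace=False))
            assert ml.loocv_accuracy(planted_matrix, sub, 3) == pytest.approx(
                ml.loocv_accuracy_slow(planted_matrix, sub, 3))

    def test_unknown_feature_rejected(self, planted_matrix):
        with pytest.raises(ValueError, match="unknown feature"):
            ml.loocv_accuracy(planted_matrix, ["nope"], 3)

    def test_uninformative_features_near_majority_rate(self):
        """With labels independent of features, LOOCV hovers at the
        majority-class rate rather than at chance 50%."""
        spec = FeatureGenSpec(n_active=60, n_inactive=120, planted=(),
                              seed=5)
        m = make_feature_dataset(spec)
        acc = ml.loocv_accuracy(m, ["H3.2f", "H4.1s", "H5.3l"], k=3)
        assert abs(acc - 100 * 120 / 180) < 15.0

    def test_dummy_loocv_is_majority_fraction(self):
        labels = np.array([0] * 18 + [1] * 9)
        assert ml.dummy_loocv_accuracy(labels) == pytest.approx(100 * 18 / 27)


class TestBootstrap:
    def test_perfect_separator_mean_100_se_0(self):
        m = _separating_matrix()
        cfg = AnalysisConfig(rng_seed=0, bootstrap_iters=300)
        mean, se = ml.bootstrap_accuracy(m, ["H2.2s", "H1.1l"], 3, cfg)
        assert mean == pytest.approx(100.0)
        assert se == pytest.approx(0.0)

    def test_same_seed_reproducible(self, planted_matrix):
        cfg = AnalysisConfig(rng_seed=7, bootstrap_iters=500)
        a = ml.bootstrap_accuracy(planted_matrix, ["ECL1l", "H2.2s"], 3, cfg)
        b = ml.bootstrap_accuracy(planted_matrix, ["ECL1l", "H2.2s"], 3, cfg)
        assert a == b

    def test_dummy_mean_matches_independent_simulation(self):
        """Dummy out-of-bag accuracy against a from-scratch resampling
        simulation of the majority-class predictor."""
        labels = np.array([0] * 18 + [1] * 9, dtype=np.int8)
        data = np.zeros((27, len(FEATURE_NAMES)), dtype=np.int8)
        m = FeatureMatrix([f"s{i}" for i in range(27)], data, labels)
        iters = 4000
        cfg = AnalysisConfig(rng_seed=11, bootstrap_iters=iters)
        mean, se = ml.bootstrap_accuracy(m, None, 3, cfg)
        rng = np.random.default_rng(999)
        sim = []
        for _ in range(iters):
            train = rng.integers(0, 27, 27)
            oob = np.setdiff1d(np.arange(27), train)
            if oob.size == 0:
                continue
            y_train = labels[train]
            if y_train.min() == y_train.max():
                continue
            majority = 1 if y_train.sum() * 2 > 27 else 0
            sim.append(100.0 * (labels[oob] == majority).mean())
        sim = np.array(sim)
        tol = 3 * (se / np.sqrt(len(sim)) + sim.std() / np.sqrt(len(sim)))
        assert abs(mean - sim.mean()) < tol


class TestSubsetSearch:
    def test_forward_sfs_finds_separator_first(self):
        m = _separating_matrix()
        traj = ml.sfs_trajectory(m, 3, "forward", False, target_size=3)
        assert traj.best_by_size[1][1] == ("H2.2s",)
        assert traj.best_by_size[1][0] == 100.0

    def test_backward_sfs_keeps_separator(self, planted_matrix):
        m = _separating_matrix()
        final = ml.sfs_select(m, 3, "backward", False, target_size=2)
        assert "H2.2s" in final

    def test_floating_never_worse_than_plain(self, planted_matrix):
        plain = ml.sfs_trajectory(planted_matrix, 3, "forward", False, 6)
        floating = ml.sfs_trajectory(planted_matrix, 3, "forward", True, 6)
        best_plain = max(acc for acc, _ in plain.best_by_size.values())
        best_float = max(acc for acc, _ in floating.best_by_size.values())
        assert best_float >= best_plain

    def test_target_size_must_be_below_feature_count(self, planted_matrix):
        with pytest.raises(ValueError):
            ml.sfs_select(planted_matrix, 3, "forward", False, target_size=87)

    def test_efs_enumerates_expected_count(self, planted_matrix):
        cfg = AnalysisConfig(max_subset_size=3)
        names = list(FEATURE_NAMES[:10])
        results = ml.efs_select(planted_matrix, names, 3, cfg)
        assert len(results) == 10 + 45 + 120

    def test_efs_ranking_prefers_accuracy_then_size(self, planted_matrix):
        cfg = AnalysisConfig(max_subset_size=3)
        results = ml.efs_select(planted_matrix, list(FEATURE_NAMES[:10]), 3,
                                cfg)
        keys = [(-r.loocv_accuracy, len(r.subset), r.subset) for r in results]
        assert keys == sorted(keys)

    def test_efs_guard_triggers(self, planted_matrix):
        cfg = AnalysisConfig(max_subset_size=8, efs_guard=1000)
        with pytest.raises(ValueError, match="guard"):
            ml.efs_select(planted_matrix, list(FEATURE_NAMES[:30]), 3, cfg)

    def test_efs_bounds_sfs_from_above(self, planted_matrix):
        """The exhaustive optimum over the same candidates is at least as
        good as any sequential selection."""
        cfg = AnalysisConfig(max_subset_size=4)
        names = sorted(FEATURE_NAMES[i] for i in range(0, 87, 7))
        traj = ml.sfs_trajectory(planted_matrix, 3, "forward", False, 4,
                                 candidate_features=names)
        best_sfs = max(acc for acc, _ in traj.best_by_size.values())
        top = ml.efs_select(planted_matrix, names, 3, cfg, limit=1)[0]
        assert top.loocv_accuracy >= best_sfs


class TestMCC:
    def _matrix(self, cols):
        data = np.zeros((len(cols[0]), len(FEATURE_NAMES)), dtype=np.int8)
        names = []
        for i, col in enumerate(cols):
            data[:, i] = col
            names.append(FEATURE_NAMES[i])
        labels = np.array([0, 1] * (len(cols[0]) // 2)
                          + [0] * (len(cols[0]) % 2), dtype=np.int8)
        return FeatureMatrix([f"s{i}" for i in range(len(cols[0]))],
                             data, labels), names

    def test_identical_columns(self):
        m, names = self._matrix([[1, 0, 1, 0], [1, 0, 1, 0]])
        mat = ml.mcc_matrix(m, names)
        assert mat[0, 1] == pytest.approx(1.0)

    def test_complementary_columns(self):
        m, names = self._matrix([[1, 0, 1, 0], [0, 1, 0, 1]])
        assert ml.mcc_matrix(m, names)[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        m, names = self._matrix([rng.integers(0, 2, 1000),
                                 rng.integers(0, 2, 1000)])
        assert abs(ml.mcc_matrix(m, names)[0, 1]) < 0.1

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rng.integers(0, 2, 60), rng.integers(0, 2, 60)
            m, names = self._matrix([a, b])
            ours = ml.mcc_matrix(m, names)[0, 1]
            theirs = sklearn_metrics.matthews_corrcoef(a, b)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_symmetric_unit_diagonal(self, planted_matrix):
        sub = ["ECL1l", "H2.2s", "H3.1f", "H5.1l"]
        mat = ml.mcc_matrix(planted_matrix, sub)
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert (np.abs(mat) <= 1.0 + 1e-12).all()


class TestDiscovery:
    def test_deterministic_given_seed(self, planted_matrix):
        cfg = AnalysisConfig(rng_seed=5, bootstrap_iters=100)
        a = ml.run_signature_discovery(planted_matrix, cfg, top_n=2)
        b = ml.run_signature_discovery(planted_matrix, cfg, top_n=2)
        assert a.chosen_signature == b.chosen_signature
        assert a.top[0].bootstrap_mean == b.top[0].bootstrap_mean

    def test_dummy_baseline_reported(self, planted_matrix):
        cfg = AnalysisConfig(rng_seed=5, bootstrap_iters=100)
        res = ml.run_signature_discovery(planted_matrix, cfg, top_n=1)
        assert res.dummy.loocv_accuracy == pytest.approx(100 * 18 / 27)

    def test_chosen_features_come_from_planted_signal(self, planted_matrix):
        res = ml.run_signature_discovery(planted_matrix, with_bootstrap=False)
        planted = {"ECL1l", "H2.2s", "H3.1f", "H5.1l"}
        assert set(res.chosen_signature) & planted

    def test_shuffled_labels_fall_below_planted_top(self, planted_matrix):
        """Permuting labels breaks the planted signal: the permuted optimum
        stays below the genuine one."""
        genuine = ml.run_signature_discovery(planted_matrix,
                                             with_bootstrap=False)
        rng = np.random.default_rng(17)
        shuffled = FeatureMatrix(planted_matrix.structure_ids,
                                 planted_matrix.data,
                                 rng.permutation(planted_matrix.labels))
        null = ml.run_signature_discovery(shuffled, with_bootstrap=False)
        assert (null.ranked[0].loocv_accuracy
                <= genuine.ranked[0].loocv_accuracy)
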