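"""k-NN prediction and cross-validation: oracle equality of the two engines."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from eknn.dataset import make_separable_fixture, simulate_uniform
from eknn.distance import denovo_matrix
from eknn.knn import (build_neighbor_table, cv_error_fast, cv_error_naive,
                      knn_predict, loo_error, make_folds)


class TestKnnPredict:
    def test_nearest_wins_k1(self):
        assert knn_predict([0.5, 0.1], [0, 1], k=1) == 1

    def test_vote_tie_goes_to_first_encoded_label(self):
        assert knn_predict([0.1, 0.2], [1, 0], k=2) == 0

    def test_majority_of_three(self):
        assert knn_predict([0.1, 0.2, 0.3, 0.9], [0, 1, 1, 0], k=3) == 1

    def test_distance_tie_broken_by_index(self):
        # both at distance 0.2; the earlier training sample joins the vote
        assert knn_predict([0.1, 0.2, 0.2], [0, 1, 0], k=2) == 0

    def test_k_exceeding_training_raises(self):
        with pytest.raises(ValueError):
            knn_predict([0.1, 0.2], [0, 1], k=3)


class TestMakeFolds:
    def test_equal_fold_sizes(self):
        plan = make_folds(20, r=10, f=10, seed=3)
        for run in range(10):
            assert np.bincount(plan.assignments[run]).tolist() == [2] * 10

    def test_remainder_distribution(self):
        plan = make_folds(23, r=4, f=10, seed=0)
        for run in range(4):
            sizes = sorted(np.bincount(plan.assignments[run]), reverse=True)
            assert sizes == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_determinism(self):
        a = make_folds(30, 5, 10, seed=7)
        b = make_folds(30, 5, 10, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        c = make_folds(30, 5, 10, seed=8)
        assert (a.assignments != c.assignments).any()

    def test_f_exceeding_m_raises(self):
        with pytest.raises(ValueError):
            make_folds(5, 1, 6, seed=0)


class TestNaiveCv:
    def test_separable_feature_zero_error(self, separable_20x4):
        D = denovo_matrix(separable_20x4, (2,))
        plan = make_folds(20, r=3, f=10, seed=5)
        assert cv_error_naive(D, separable_20x4.labels, 1, plan).error == 0.0

    def test_uniform_labels_zero_error(self):
        d = simulate_uniform(10, 2, 1, seed=0)
        D = denovo_matrix(d, (1, 2))
        plan = make_folds(10, r=2, f=5, seed=1)
        assert cv_error_naive(D, d.labels, 1, plan).error == 0.0

    def test_hand_enumerated_toy(self):
        # four points on a line at 0, 1, 5, 6; labels 0,0,1,1; 2 folds:
        # {0,1} vs {5,6}. Held-out 0 -> nearest training is 5 -> wrong, etc.
        D = np.abs(np.subtract.outer([0.0, 1, 5, 6], [0.0, 1, 5, 6]))
        y = np.array([0, 0, 1, 1])
        plan = make_folds(4, r=1, f=2, seed=0)
        plan.assignments[0] = [0, 0, 1, 1]
        plan._train_cache.clear()
        res = cv_error_naive(D, y, 1, plan)
        assert res.error == 1.0  # every sample's nearest cross-fold point is the other class

    def test_against_sklearn_oracle(self):
        """Per-fold predictions match an independent sklearn k-NN (k=1)."""
        d = simulate_uniform(24, 4, 2, seed=21)
        D = denovo_matrix(d, (1, 2, 3, 4)).values
        plan = make_folds(24, r=2, f=6, seed=2)
        preds = np.empty((2, 24), dtype=int)
        cv_error_naive(D, d.labels, 1, plan, out_predictions=preds)
        for run in range(2):
            for fold in range(6):
                train = plan.train_indices(run, fold)
                test = np.flatnonzero(plan.assignments[run] == fold)
                clf = KNeighborsClassifier(n_neighbors=1).fit(
                    d.features[train], d.labels[train])
                np.testing.assert_array_equal(
                    preds[run, test], clf.predict(d.features[test]))


class TestNeighborTable:
    def test_three_collinear_points(self):
        # squared distances between 0, 1, 3: pairs (1, 9, 4)
        x = np.array([0.0, 1.0, 3.0])
        D = (x[:, None] - x[None, :]) ** 2
        t = build_neighbor_table(D, 1)
        assert t.neighbors[:, 0].tolist() == [1, 0, 1]

    def test_k_equals_m_minus_one_sorts_everything(self, uniform_10x6):
        D = denovo_matrix(uniform_10x6, (1, 2, 3))
        t = build_neighbor_table(D, 9)
        for s in range(10):
            assert sorted(t.neighbors[s]) == [i for i in range(10) if i != s]
            assert (np.diff(t.distances[s]) >= 0).all()

    def test_k_too_large_raises(self, uniform_10x6):
        D = denovo_matrix(uniform_10x6, (1,))
        with pytest.raises(ValueError):
            build_neighbor_table(D, 10)


class TestFastCv:
    @pytest.mark.parametrize("m,n,k,f,r,n_classes,seed", [
        (30, 6, 1, 10, 3, 2, 0),
        (30, 6, 3, 10, 3, 2, 1),
        (25, 4, 2, 5, 2, 3, 2),    # uneven folds, multi-class, even k
        (12, 3, 5, 3, 4, 2, 3),
    ])
    def test_identical_predictions_to_naive(self, m, n, k, f, r, n_classes, seed):
        d = simulate_uniform(m, n, n_classes, seed=seed)
        D = denovo_matrix(d, tuple(range(1, n + 1)))
        plan = make_folds(m, r, f, seed=seed + 100)
        table = build_neighbor_table(D, k)
        pn = np.empty((r, m), dtype=int)
        pf = np.empty((r, m), dtype=int)
        rn = cv_error_naive(D, d.labels, k, plan, out_predictions=pn)
        rf = cv_error_fast(D, d.labels, k, plan, table, out_predictions=pf)
        np.testing.assert_array_equal(pn, pf)
        np.testing.assert_array_equal(rn.per_run_errors, rf.per_run_errors)
        assert rf.lookup_hits + rf.lookup_misses == r * m

    def test_duplicate_points_force_tie_handling(self):
        # repeated coordinates create exact distance ties everywhere
        feats = np.array([[0.0], [0.0], [1.0], [1.0], [1.0], [2.0]] * 2)
        from eknn.dataset import LabeledDataset
        d = LabeledDataset(features=feats, labels=np.arange(12) % 2)
        D = denovo_matrix(d, (1,))
        plan = make_folds(12, r=4, f=4, seed=9)
        for k in (1, 2, 3):
            table = build_neighbor_table(D, k)
            pn = np.empty((4, 12), dtype=int)
            pf = np.empty((4, 12), dtype=int)
            cv_error_naive(D, d.labels, k, plan, out_predictions=pn)
            cv_error_fast(D, d.labels, k, plan, table, out_predictions=pf)
            np.testing.assert_array_equal(pn, pf)

    def test_leave_one_out_plan_all_hits(self, separable_20x4):
        D = denovo_matrix(separable_20x4, (1, 2))
        plan = make_folds(20, r=1, f=20, seed=0)
        table = build_neighbor_table(D, 1)
        res = cv_error_fast(D, separable_20x4.labels, 1, plan, table)
        assert res.lookup_hits == 20 and res.lookup_misses == 0

    def test_mismatched_table_raises(self, separable_20x4):
        D = denovo_matrix(separable_20x4, (1, 2))
        plan = make_folds(20, r=1, f=10, seed=0)
        with pytest.raises(ValueError):
            cv_error_fast(D, separable_20x4.labels, 3, plan,
                          build_neighbor_table(D, 1))

    def test_relabeling_invariance(self):
        """Swapping class codes (and hence the tie order) mirrors predictions."""
        d = simulate_uniform(20, 3, 2, seed=4)
        D = denovo_matrix(d, (1, 2, 3))
        plan = make_folds(20, r=2, f=5, seed=5)
        table = build_neighbor_table(D, 3)
        p = np.empty((2, 20), dtype=int)
        cv_error_fast(D, d.labels, 3, plan, table, out_predictions=p)
        q = np.empty((2, 20), dtype=int)
        cv_error_fast(D, 1 - d.labels, 3, plan, table, out_predictions=q)
        np.testing.assert_array_equal(p, 1 - q)

    def test_expected_lookup_count_matches_hypergeometric_mean(self):
        """Mean successful lookups per test sample ~ k |T| / (|S|-1)."""
        m, f, k = 40, 10, 2
        d = simulate_uniform(m, 3, 2, seed=8)
        D = denovo_matrix(d, (1, 2, 3))
        table = build_neighbor_table(D, k)
        runs = 400
        plan = make_folds(m, runs, f, seed=13)
        per_run = np.empty(runs)
        for run in range(runs):
            fold_of = plan.assignments[run]
            in_train = fold_of[table.neighbors] != fold_of[:, None]
            per_run[run] = in_train.sum() / m
        expect = k * (m - m // f) / (m - 1)
        se = per_run.std(ddof=1) / np.sqrt(runs)
        assert abs(per_run.mean() - expect) < 3 * se + 1e-12


class TestLoo:
    def test_separable_zero(self, separable_20x4):
        D = denovo_matrix(separable_20x4, (2,))
        assert loo_error(D, separable_20x4.labels, 1) == 0.0

    def test_two_samples_cross_labels(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert loo_error(D, np.array([0, 1]), 1) == 1.0

    def test_equals_naive_with_m_folds(self):
        for seed in (1, 2, 3):
            d = simulate_uniform(15, 4, 3, seed=seed)
            D = denovo_matrix(d, (1, 3))
            plan = make_folds(15, r=1, f=15, seed=0)
            for k in (1, 4):
                assert loo_error(D, d.labels, k) == pytest.approx(
                    cv_error_naive(D, d.labels, k, plan).error)
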