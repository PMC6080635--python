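"""Conditional inference tree: association statistic, split search, growth."""

import numpy as np
import pytest

from sensewin import (
    CTreeParams,
    best_binary_split,
    fit_ctree,
    linear_association_statistic,
    predict_tree,
    select_split_variable,
)
from sensewin.ctree import tree_from_json, tree_to_json

from oracles import asymptotic_p_tolerance, brute_force_split, exact_permutation_pvalue


class TestAssociationStatistic:
    def test_constant_regressor_is_degenerate(self):
        stat, p = linear_association_statistic([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        assert stat == 0.0 and p == 1.0

    def test_constant_response_is_degenerate(self):
        stat, p = linear_association_statistic([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert stat == 0.0 and p == 1.0

    def test_orthogonal_case_has_p_one(self):
        stat, p = linear_association_statistic([1, 0, 1, 0], [1, 1, -1, -1])
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "x, y",
        [([1.0], [2.0]), ([1.0, 2.0], [1.0, 2.0, 3.0])],
    )
    def test_input_validation(self, x, y):
        with pytest.raises(ValueError):
            linear_association_statistic(x, y)

    def test_matches_exact_permutation_p_on_canonical_case(self):
        # exhaustive: C(4,2) = 6 distinct assignments, 2 as extreme => 1/3
        x = [0.0, 0.0, 1.0, 1.0]
        y = [0.0, 0.0, 1.0, 1.0]
        assert exact_permutation_pvalue(x, y) == pytest.approx(1 / 3)
        _, p = linear_association_statistic(x, y)
        assert abs(p - 1 / 3) < asymptotic_p_tolerance(4)

    def test_asymptotic_p_tracks_exact_p_on_small_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 9))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, p = linear_association_statistic(x, y)
            p_exact = exact_permutation_pvalue(x, y)
            assert abs(p - p_exact) < asymptotic_p_tolerance(n)


class TestSelectSplitVariable:
    def test_single_candidate_is_chosen(self, rng):
        X = rng.normal(size=(10, 3))
        chosen, pvals = select_split_variable(X, rng.normal(size=10), [2])
        assert chosen == 2 and set(pvals) == {2}

    def test_empty_candidate_set_errors(self, rng):
        with pytest.raises(ValueError):
            select_split_variable(rng.normal(size=(5, 2)), rng.normal(size=5), [])

    def test_constant_candidates_report_p_one(self, rng):
        X = np.ones((8, 3))
        _, pvals = select_split_variable(X, rng.normal(size=8), [0, 1, 2])
        assert all(p == 1.0 for p in pvals.values())

    def test_true_signal_column_wins(self, rng):
        # y is literally column 1; noise columns should essentially never win
        wins = 0
        runs = 200
        for _ in range(runs):
            X = rng.normal(size=(30, 3))
            y = X[:, 1].copy()
            chosen, _ = select_split_variable(X, y, [0, 1, 2])
            wins += chosen == 1
        assert wins >= int(0.99 * runs)

    def test_selection_agrees_with_exact_permutation_oracle(self, rng):
        """On clear-cut small instances the asymptotic argmin matches the
        exact-permutation argmin; near-ties (exact gap < 0.1) are exempt."""
        checked = 0
        for _ in range(60):
            n = int(rng.integers(5, 9))
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            chosen, _ = select_split_variable(X, y, [0, 1, 2])
            exact = np.array([exact_permutation_pvalue(X[:, j], y) for j in range(3)])
            gaps = np.sort(exact)
            if gaps[1] - gaps[0] < 0.1:
                continue
            assert chosen == int(np.argmin(exact))
            checked += 1
        assert checked >= 20  # the instance distribution must actually exercise it


class TestBestBinarySplit:
    def test_clean_two_group_separation(self):
        thr, _ = best_binary_split([1, 2, 3, 4], [0, 0, 10, 10], min_bucket=1)
        assert thr == pytest.approx(2.5)

    def test_binary_predictor_single_cutpoint(self):
        thr, _ = best_binary_split([0, 1, 0, 1, 1], [1.0, 2.0, 1.5, 2.5, 3.0], min_bucket=1)
        assert thr == pytest.approx(0.5)

    def test_min_bucket_blocks_all_cutpoints(self):
        assert best_binary_split([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0], min_bucket=3) is None

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 12))
            x = rng.choice([0.0, 1.0, 2.0, 3.0], size=n)
            y = rng.normal(size=n)
            mb = int(rng.integers(1, 3))
            got = best_binary_split(x, y, min_bucket=mb)
            want = brute_force_split(x, y, min_bucket=mb)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got[0] == pytest.approx(want[0])
                assert got[1] == pytest.approx(want[1])


class TestFitAndPredict:
    def test_constant_response_gives_root_only_tree(self, rng):
        X = rng.normal(size=(30, 4))
        tree = fit_ctree(X, np.full(30, 3.5), CTreeParams(mtry=2), rng)
        assert tree.is_terminal and tree.prediction == pytest.approx(3.5)

    def test_small_node_gives_root_only_tree(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        tree = fit_ctree(X, y, CTreeParams(mtry=2, min_split=8), rng)
        assert tree.is_terminal and tree.prediction == pytest.approx(y.mean())

    def test_perfect_binary_separator_fits_two_leaves(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]] * 2)
        y = np.where(X[:, 0] == 0, 1.0, 9.0)
        tree = fit_ctree(X, y, CTreeParams(mtry=1, min_split=2, min_bucket=1, alpha=1.0), 0)
        assert not tree.is_terminal
        assert tree.left.prediction == pytest.approx(1.0)
        assert tree.right.prediction == pytest.approx(9.0)

    def test_missing_values_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError):
            fit_ctree(X, rng.normal(size=10), CTreeParams(mtry=2), rng)

    def test_terminal_predictions_are_node_means(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0] * 2 + rng.normal(size=60)
        tree = fit_ctree(X, y, CTreeParams(mtry=2, min_split=6, min_bucket=2), 3)

        def check(node, idx):
            if node.is_terminal:
                assert node.n == len(idx)
                assert node.prediction == pytest.approx(y[idx].mean())
                return
            left = X[idx, node.split_var] <= node.threshold
            assert node.left.n + node.right.n == node.n
            check(node.left, idx[left])
            check(node.right, idx[~left])

        check(tree, np.arange(60))

    def test_smaller_alpha_never_grows_deeper(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 0] + 0.5 * rng.normal(size=50)
        depths = []
        for alpha in (0.05, 0.5, 1.0):
            tree = fit_ctree(X, y, CTreeParams(mtry=3, min_split=6, min_bucket=2, alpha=alpha), 5)
            depths.append(tree.depth())
        assert depths == sorted(depths)

    def test_root_only_tree_predicts_constant(self, rng):
        X = rng.normal(size=(10, 2))
        tree = fit_ctree(X, np.full(10, 2.0), CTreeParams(mtry=1), rng)
        assert np.all(predict_tree(tree, rng.normal(size=(7, 2))) == 2.0)

    def test_deep_tree_refines_root_mse(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 1] + rng.normal(size=40)
        tree = fit_ctree(X, y, CTreeParams(mtry=3, min_split=2, min_bucket=1, alpha=1.0), 1)
        mse_tree = np.mean((predict_tree(tree, X) - y) ** 2)
        mse_root = np.mean((y - y.mean()) ** 2)
        assert mse_tree <= mse_root + 1e-12

    def test_case_at_threshold_routes_left(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0], [0.0], [1.0]])
        y = np.array([1.0, 1.0, 9.0, 9.0, 1.0, 9.0])
        tree = fit_ctree(X, y, CTreeParams(mtry=1, min_split=2, min_bucket=1), 0)
        assert not tree.is_terminal
        at_thr = np.array([[tree.threshold]])
        assert predict_tree(tree, at_thr)[0] == pytest.approx(tree.left.prediction)

    def test_wrong_column_count_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 2] + rng.normal(size=20)
        tree = fit_ctree(X, y, CTreeParams(mtry=3, min_split=4, min_bucket=1), 0)
        with pytest.raises(ValueError):
            predict_tree(tree, X[:, :2])

    def test_json_round_trip_preserves_predictions(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(size=30)
        tree = fit_ctree(X, y, CTreeParams(mtry=2, min_split=4, min_bucket=1), 2)
        clone = tree_from_json(tree_to_json(tree))
        assert np.allclose(predict_tree(tree, X), predict_tree(clone, X))
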