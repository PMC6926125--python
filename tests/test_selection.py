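import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from lpivec import (
    ClassNode,
    ImportanceReport,
    forest_importance,
    gini_index,
    node_importance,
    rank_features,
    select_top_k,
)
from lpivec.selection import tree_from_sklearn


def leaf(p, n=10):
    return ClassNode(np.asarray(p, dtype=float), n)


def split(p, feature, left, right, n=10):
    return ClassNode(np.asarray(p, dtype=float), n, split_feature=feature, left=left, right=right)


def brute_force_vim(roots, m, weighted=False):
    """Independent node-by-node traversal: GI = 1 - sum p^2, importance of a
    branching = GI_parent - GI_right - GI_left, summed per split feature.
    The weighted variant scales children by their sample fractions and the
    whole decrease by the fraction of tree samples reaching the node."""
    raw = [0.0] * m
    def gi(node):
        return 1.0 - sum(p * p for p in node.class_proportions)
    def walk(node, root_n):
        if node.is_leaf:
            return
        if weighted:
            dec = gi(node) - (node.right.sample_count / node.sample_count) * gi(node.right) \
                - (node.left.sample_count / node.sample_count) * gi(node.left)
            dec *= node.sample_count / root_n
        else:
            dec = gi(node) - gi(node.right) - gi(node.left)
        raw[node.split_feature] += dec
        walk(node.left, root_n)
        walk(node.right, root_n)
    for r in roots:
        walk(r, r.sample_count)
    return raw


def random_tree(rng, depth, m, n_classes=2):
    p = rng.dirichlet(np.ones(n_classes))
    n = int(rng.integers(2, 40))
    if depth == 0 or rng.random() < 0.3:
        return ClassNode(p, n)
    return ClassNode(
        p, n,
        split_feature=int(rng.integers(0, m)),
        left=random_tree(rng, depth - 1, m, n_classes),
        right=random_tree(rng, depth - 1, m, n_classes),
    )


class TestGiniIndex:
    @pytest.mark.parametrize(
        "proportions, expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 0.5), ((0.25, 0.75), 0.375)],
    )
    def test_hand_values(self, proportions, expected):
        assert gini_index(leaf(proportions)) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_one_minus_inverse_k(self, rng):
        for k in (2, 3, 5):
            for _ in range(20):
                g = gini_index(leaf(rng.dirichlet(np.ones(k))))
                assert 0.0 <= g <= 1.0 - 1.0 / k + 1e-12

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            gini_index(ClassNode(np.array([0.5, 0.2]), 10))


class TestNodeImportance:
    def test_direct_subtraction(self):
        # impurities 0.5, 0.2, 0.1 -> 0.5 - 0.2 - 0.1 = 0.2
        p_left = (0.5 * (1 + np.sqrt(1 - 2 * 0.2)), 0.5 * (1 - np.sqrt(1 - 2 * 0.2)))
        p_right = (0.5 * (1 + np.sqrt(1 - 2 * 0.1)), 0.5 * (1 - np.sqrt(1 - 2 * 0.1)))
        left, right = leaf(p_left), leaf(p_right)
        parent = split((0.5, 0.5), 0, left, right)
        assert gini_index(left) == pytest.approx(0.2)
        assert gini_index(right) == pytest.approx(0.1)
        assert node_importance(parent, left, right) == pytest.approx(0.2)

    def test_pure_family_zero(self):
        parent = split((1.0, 0.0), 0, leaf((1.0, 0.0)), leaf((1.0, 0.0)))
        assert node_importance(parent, parent.left, parent.right) == 0.0

    def test_perfect_split_of_balanced_node(self):
        parent = split((0.5, 0.5), 0, leaf((1.0, 0.0)), leaf((0.0, 1.0)))
        assert node_importance(parent, parent.left, parent.right) == pytest.approx(0.5)

    def test_leaf_parent_rejected(self):
        with pytest.raises(ValueError):
            node_importance(leaf((0.5, 0.5)), leaf((1, 0)), leaf((0, 1)))

    def test_weighted_variant_scales_children(self):
        parent = split((0.5, 0.5), 0, leaf((1.0, 0.0), n=6), leaf((0.25, 0.75), n=4), n=10)
        expected = 0.5 - (4 / 10) * 0.375 - (6 / 10) * 0.0
        assert node_importance(parent, parent.left, parent.right, weighted=True) == pytest.approx(expected)


class TestForestImportance:
    def test_two_single_split_trees_accumulate(self):
        t1 = split((0.5, 0.5), 0,
                   leaf((0.5 * (1 + np.sqrt(0.6)), 0.5 * (1 - np.sqrt(0.6)))),
                   leaf((0.5 * (1 + np.sqrt(0.8)), 0.5 * (1 - np.sqrt(0.8)))))
        # impurity decrease of t1 = 0.5 - 0.2 - 0.1 = 0.2
        t2 = split((0.5, 0.5), 0, leaf((1.0, 0.0)), leaf((0.5 * (1 + np.sqrt(0.6)), 0.5 * (1 - np.sqrt(0.6)))))
        # decrease of t2 = 0.5 - 0.2 - 0 = 0.3
        report = forest_importance([t1, t2], m=3)
        assert report.raw_vim[0] == pytest.approx(0.5)
        assert report.raw_vim[1] == report.raw_vim[2] == 0.0

    def test_normalization(self):
        trees = [
            split((0.5, 0.5), i, leaf((1.0, 0.0)), leaf((0.0, 1.0)))
            for i in (0, 1, 1, 2, 2, 2)  # raw (0.5, 1.0, 1.5)
        ]
        report = forest_importance(trees, m=4)
        assert np.allclose(report.raw_vim, [0.5, 1.0, 1.5, 0.0])
        assert np.allclose(report.normalized_vim, [1 / 6, 2 / 6, 3 / 6, 0.0])
        assert report.normalized_vim.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_oracle_on_random_trees(self, rng):
        m = 6
        for trial in range(30):
            roots = [random_tree(rng, depth=3, m=m) for _ in range(int(rng.integers(1, 5)))]
            if all(r.is_leaf for r in roots):
                continue
            for weighted in (False, True):
                report = forest_importance(roots, m, weighted=weighted)
                oracle = brute_force_vim(roots, m, weighted=weighted)
                assert np.allclose(report.raw_vim, oracle, atol=0)

    def test_sklearn_tree_conversion_matches_sklearn_importances(self, rng):
        # the conventional weighted form, normalised, equals sklearn's own
        # impurity-based importances on a single tree
        X = rng.normal(size=(120, 5))
        y = (X[:, 2] + 0.5 * X[:, 0] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=3, random_state=0).fit(X, y)
        report = forest_importance([tree], m=5, weighted=True)
        assert report.normalized_vim == pytest.approx(tree.feature_importances_, abs=1e-9)

    def test_empty_forest_rejected(self):
        with pytest.raises(ValueError):
            forest_importance([], m=3)

    def test_all_leaf_forest_flagged_degenerate(self):
        report = forest_importance([leaf((0.5, 0.5))], m=3)
        assert report.degenerate
        assert report.normalized_vim is None


class TestSelectTopK:
    def test_top_k_of_m(self):
        report = ImportanceReport(np.array([2.0, 3.0, 5.0]), np.array([0.2, 0.3, 0.5]), 1)
        mask = select_top_k(report, 2)
        assert mask.selected_indices == (2, 1)

    def test_k_exceeding_m_returns_all(self):
        report = ImportanceReport(np.arange(30, dtype=float), None, 1)
        report.normalized_vim = report.raw_vim / report.raw_vim.sum()
        assert len(select_top_k(report, 50)) == 30

    def test_ties_broken_by_ascending_index(self):
        report = ImportanceReport(np.ones(4), np.full(4, 0.25), 1)
        assert select_top_k(report, 2).selected_indices == (0, 1)

    def test_mask_apply(self):
        report = ImportanceReport(np.array([1.0, 3.0, 2.0]), np.array([1 / 6, 3 / 6, 2 / 6]), 1)
        mask = select_top_k(report, 2)
        X = np.arange(6).reshape(2, 3)
        assert np.array_equal(mask.apply(X), X[:, [1, 2]])


class TestRankFeatures:
    def test_planted_signal_recovery(self):
        """Features 0..9 carry the class signal; at least 8 of the top 10
        selected features should come from that set (majority over 5 seeds)."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, size=400)
            X = rng.normal(size=(400, 60))
            X[:, :10] += (2 * y[:, None] - 1) * 0.8  # class shift on features 0..9 only
            report, _ = rank_features(X, y, n_trees=200, seed=seed)
            top10 = set(select_top_k(report, 10).selected_indices)
            if len(top10 & set(range(10))) >= 8:
                hits += 1
        assert hits >= 3

    def test_normalized_sums_to_one(self, rng):
        X = rng.normal(size=(80, 12))
        y = (X[:, 0] > 0).astype(int)
        report, _ = rank_features(X, y, n_trees=20, seed=0)
        assert report.normalized_vim.sum() == pytest.approx(1.0, abs=1e-9)
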