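"""Gini-impurity variable importance over a decision-tree ensemble, and top-k selection.

At a tree node with class proportions p_k, the Gini index is
GI = 1 - sum_k p_k^2.  The importance a split contributes to its feature is
the impurity variation across the branching, GI_parent - GI_right - GI_left,
taken literally in unweighted form; the conventional child-size-weighted
decrease is available behind ``weighted=True``.  Per-feature importances are
summed over all split nodes of all trees in the ensemble and normalised to
sum to one.  Selection keeps the top-k features by normalised importance
(default 50), ties broken by ascending feature index for determinism.

Forests are fitted with scikit-learn; the importance computation itself
traverses the fitted trees node by node rather than reading
``feature_importances_``, so the unweighted form can be computed and the
arithmetic stays inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ClassNode",
    "ImportanceReport",
    "SelectionMask",
    "gini_index",
    "node_importance",
    "tree_from_sklearn",
    "forest_importance",
    "select_top_k",
    "rank_features",
]

_PROPORTION_TOL = 1e-6


@dataclass
class ClassNode:
    """A node of a classification tree, described by its class proportions.

    A leaf has no children; an internal node records the feature it splits
    on and its (left, right) children.
    """

    class_proportions: np.ndarray
    sample_count: int
    split_feature: Optional[int] = None
    left: Optional["ClassNode"] = None
    right: Optional["ClassNode"] = None

    def __post_init__(self):
        self.class_proportions = np.asarray(self.class_proportions, dtype=np.float64)
        if (self.left is None) != (self.right is None):
            raise ValueError("node must have zero or two children")
        if self.left is not None and self.split_feature is None:
            raise ValueError("internal node must record its split feature")

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ImportanceReport:
    """Per-feature Gini importances, raw and normalised to unit sum.

    ``normalized_vim`` is None when no split contributed any impurity
    decrease (degenerate forest), flagged via ``degenerate``.
    """

    raw_vim: np.ndarray
    normalized_vim: Optional[np.ndarray]
    n_trees: int

    @property
    def degenerate(self) -> bool:
        return self.normalized_vim is None

    @property
    def n_features(self) -> int:
        return self.raw_vim.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("feature_index\traw_vim\tnormalized_vim\n")
            for i, raw in enumerate(self.raw_vim):
                norm = self.normalized_vim[i] if self.normalized_vim is not None else float("nan")
                fh.write(f"{i}\t{raw:.10g}\t{norm:.10g}\n")


@dataclass(frozen=True)
class SelectionMask:
    """Indices of the selected features, ordered by descending importance."""

    selected_indices: tuple
    k_requested: int

    def __post_init__(self):
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be unique")
        if self.k_requested < 1:
            raise ValueError("k_requested must be >= 1")

    def __len__(self) -> int:
        return len(self.selected_indices)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, list(self.selected_indices)]

    def to_file(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            for i in self.selected_indices:
                fh.write(f"{i}\n")


def gini_index(node: Union[ClassNode, np.ndarray, Sequence[float]]) -> float:
    """Gini impurity 1 - sum_k p_k^2 of a node's class proportions."""
    p = node.class_proportions if isinstance(node, ClassNode) else np.asarray(node, dtype=np.float64)
    if p.ndim != 1 or (p < -_PROPORTION_TOL).any():
        raise ValueError("class proportions must be a non-negative vector")
    if abs(p.sum() - 1.0) > _PROPORTION_TOL:
        raise ValueError(f"class proportions sum to {p.sum()}, not 1")
    return float(1.0 - np.square(p).sum())


def node_importance(
    parent: ClassNode, left: ClassNode, right: ClassNode, weighted: bool = False
) -> float:
    """Impurity variation across one branching: GI_parent - GI_right - GI_left.

    With ``weighted=True`` the children are scaled by their sample
    fractions (the conventional impurity-decrease form).
    """
    if parent.is_leaf:
        raise ValueError("parent must be an internal node")
    gi_p, gi_l, gi_r = gini_index(parent), gini_index(left), gini_index(right)
    if weighted:
        n = parent.sample_count
        if n <= 0:
            raise ValueError("parent sample_count must be positive")
        return gi_p - (right.sample_count / n) * gi_r - (left.sample_count / n) * gi_l
    return gi_p - gi_r - gi_l


def _iter_splits(root: ClassNode):
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            yield node
            stack.append(node.left)
            stack.append(node.right)


def tree_from_sklearn(tree) -> ClassNode:
    """Convert a fitted sklearn decision tree (its ``tree_`` attribute is
    accepted too) into a :class:`ClassNode` structure."""
    t = getattr(tree, "tree_", tree)
    values = np.asarray(t.value)[:, 0, :]  # [n_nodes, n_classes]
    row_sums = values.sum(axis=1, keepdims=True)
    proportions = values / np.where(row_sums > 0, row_sums, 1.0)
    counts = np.asarray(t.n_node_samples)

    def build(i: int) -> ClassNode:
        if t.children_left[i] == -1:
            return ClassNode(proportions[i], int(counts[i]))
        return ClassNode(
            proportions[i],
            int(counts[i]),
            split_feature=int(t.feature[i]),
            left=build(int(t.children_left[i])),
            right=build(int(t.children_right[i])),
        )

    return build(0)


def forest_importance(
    forest: Union[RandomForestClassifier, Sequence],
    m: int,
    weighted: bool = False,
) -> ImportanceReport:
    """Accumulate per-feature Gini importance over every split of every tree.

    ``forest`` may be a fitted RandomForestClassifier, a sequence of fitted
    sklearn trees, or a sequence of :class:`ClassNode` roots.  ``m`` is the
    feature count (features never split on score zero).
    """
    if isinstance(forest, RandomForestClassifier):
        trees: List = list(forest.estimators_)
    else:
        trees = list(forest)
    if not trees:
        raise ValueError("empty forest")
    roots = [t if isinstance(t, ClassNode) else tree_from_sklearn(t) for t in trees]
    raw = np.zeros(m)
    for root in roots:
        for node in _iter_splits(root):
            if not 0 <= node.split_feature < m:
                raise ValueError(f"split feature {node.split_feature} outside [0, {m})")
            contribution = node_importance(node, node.left, node.right, weighted=weighted)
            if weighted:
                # conventional form additionally scales by the fraction of
                # the tree's samples reaching the node
                contribution *= node.sample_count / root.sample_count
            raw[node.split_feature] += contribution
    total = raw.sum()
    normalized = raw / total if total > 0 else None
    return ImportanceReport(raw_vim=raw, normalized_vim=normalized, n_trees=len(roots))


def select_top_k(report: ImportanceReport, k: int) -> SelectionMask:
    """The min(k, m) highest-importance features, ties broken by ascending index."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    scores = report.normalized_vim if report.normalized_vim is not None else report.raw_vim
    m = report.n_features
    order = np.lexsort((np.arange(m), -scores))
    return SelectionMask(tuple(int(i) for i in order[: min(k, m)]), k_requested=k)


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    weighted: bool = True,
) -> Tuple[ImportanceReport, RandomForestClassifier]:
    """Fit an importance forest on (X, y) and score every feature.

    The forest is trained for the ranking itself (500 trees by default for
    importance stability) and returned alongside the report.  Ranking uses
    the sample-weighted impurity decrease by default: on fully grown trees
    the unweighted literal form is dominated by the many near-leaf splits
    of a handful of samples, which carry no population-level information;
    pass ``weighted=False`` for the literal form.
    """
    X = np.asarray(X)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X, np.asarray(y))
    report = forest_importance(forest, X.shape[1], weighted=weighted)
    return report, forest
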