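"""CART decision tree over categorical features, written from scratch.

The classifier mirrors the interpretable tree used in the reference
analysis: binary equality tests ``x_j == v`` at every internal node,
split quality scored by the decrease in the Gini diversity index, growth
in breadth-first order under a budget on the number of internal nodes
(default 20), and leaves labelled by majority class.  The prediction is
``y_hat = sum over leaves of label_l * I(x in leaf l)`` - exactly one
leaf indicator fires per sample.

Everything is deterministic: split ties break toward the lowest feature
index and then the smallest test value, and leaf-label ties break toward
class 0 (healthy).  After growth, subtrees whose leaves all carry the
same label are collapsed; this never changes a prediction but yields the
minimal rule set (a single-node tree when one feature value separates
the classes).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


def gini_impurity(labels) -> float:
    """Gini diversity index ``1 - p0^2 - p1^2`` of a binary label multiset."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty label set")
    p1 = float(np.mean(y))
    return 1.0 - (1.0 - p1) ** 2 - p1 ** 2


def _gini_from_counts(n0: float, n1: float) -> float:
    n = n0 + n1
    return 1.0 - (n0 / n) ** 2 - (n1 / n) ** 2


def _sorted_values(column) -> list:
    values = set(column.tolist())
    try:
        return sorted(values)
    except TypeError:
        return sorted(values, key=str)


def best_split(X, y):
    """Best equality split ``(feature j, value v, impurity decrease)``.

    Exhaustively scores every (feature, value) pair by the weighted Gini
    decrease; returns ``None`` for a pure node or when no split yields a
    strictly positive decrease.  Ties break toward the lowest feature
    index, then the smallest value (numeric order when the domain is
    numeric, lexicographic otherwise).
    """
    X = np.asarray(X, dtype=object)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 2 or len(np.unique(y)) < 2:
        return None
    parent = gini_impurity(y)
    n1_total = int(y.sum())
    best = None
    for j in range(X.shape[1]):
        column = X[:, j]
        for v in _sorted_values(column):
            mask = column == v
            n_in = int(mask.sum())
            if n_in == 0 or n_in == n:
                continue
            in1 = int(y[mask].sum())
            out1 = n1_total - in1
            n_out = n - n_in
            child = (n_in * _gini_from_counts(n_in - in1, in1)
                     + n_out * _gini_from_counts(n_out - out1, out1)) / n
            decrease = parent - child
            # 1e-12 guard: mathematically tied candidates must resolve to
            # the first-seen one regardless of float noise
            if decrease > 1e-12 and (best is None or decrease > best[2] + 1e-12):
                best = (j, v, decrease)
    return best


@dataclass
class TreeNode:
    """Internal node (``feature``/``value`` set) or leaf (``label`` set)."""

    label: int | None = None
    feature: int | None = None
    value: object = None
    match: "TreeNode | None" = None   # branch where x[feature] == value
    other: "TreeNode | None" = None   # branch where x[feature] != value
    n: int = 0
    counts: tuple[int, int] = (0, 0)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    """Fitted CART tree plus its hyperparameters."""

    root: TreeNode
    max_splits: int
    n_features: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_internal_nodes(self) -> int:
        def count(node):
            return 0 if node.is_leaf else 1 + count(node.match) + count(node.other)
        return count(self.root)

    def name(self, j: int) -> str:
        return self.feature_names[j] if self.feature_names else f"x{j + 1}"

    def to_dict(self) -> dict:
        def walk(node):
            if node.is_leaf:
                return {"label": int(node.label), "n": node.n,
                        "counts": list(node.counts)}
            return {"feature": self.name(node.feature),
                    "value": node.value, "n": node.n,
                    "counts": list(node.counts),
                    "match": walk(node.match), "other": walk(node.other)}
        return {"max_splits": self.max_splits, "tree": walk(self.root)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=str, **kwargs)


def _majority(y) -> int:
    n1 = int(np.sum(y))
    n0 = len(y) - n1
    return 1 if n1 > n0 else 0  # tie -> class 0 (healthy)


def _collapse(node: TreeNode) -> TreeNode:
    """Merge subtrees whose leaves all share one label (prediction-preserving)."""
    if node.is_leaf:
        return node
    node.match = _collapse(node.match)
    node.other = _collapse(node.other)
    if (node.match.is_leaf and node.other.is_leaf
            and node.match.label == node.other.label):
        return TreeNode(label=node.match.label, n=node.n, counts=node.counts)
    return node


def fit_tree(X, y, max_splits: int = 20,
             feature_names: Sequence[str] | None = None,
             collapse: bool = True) -> DecisionTree:
    """Grow a CART tree with equality splits and a split budget.

    Nodes are processed breadth-first; each split consumes one unit of
    the ``max_splits`` budget (internal-node count).  A node becomes a
    leaf when it is pure, no split gives a positive Gini decrease, or the
    budget is exhausted.  With ``collapse=True`` (default) label-uniform
    subtrees are merged after growth.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")

    def make_node(idx) -> TreeNode:
        sub_y = y[idx]
        n1 = int(sub_y.sum())
        return TreeNode(label=_majority(sub_y), n=len(idx),
                        counts=(len(idx) - n1, n1))

    all_idx = np.arange(X.shape[0])
    root = make_node(all_idx)
    queue: list[tuple[TreeNode, np.ndarray]] = [(root, all_idx)]
    splits_used = 0
    while queue and splits_used < max_splits:
        node, idx = queue.pop(0)
        found = best_split(X[idx], y[idx])
        if found is None:
            continue
        j, v, _ = found
        mask = X[idx, j] == v
        node.feature, node.value, node.label = j, v, None
        node.match = make_node(idx[mask])
        node.other = make_node(idx[~mask])
        splits_used += 1
        queue.append((node.match, idx[mask]))
        queue.append((node.other, idx[~mask]))

    if collapse:
        root = _collapse(root)
    return DecisionTree(root=root, max_splits=max_splits,
                        n_features=X.shape[1],
                        feature_names=list(feature_names or []))


def predict_one(tree: DecisionTree, x) -> int:
    """Class of one sample by deterministic root-to-leaf traversal."""
    x = np.asarray(x, dtype=object)
    if x.size < tree.n_features:
        raise ValueError(
            f"sample has {x.size} features, tree needs {tree.n_features}")
    node = tree.root
    while not node.is_leaf:
        node = node.match if x[node.feature] == node.value else node.other
    return int(node.label)


def predict(tree: DecisionTree, X) -> np.ndarray:
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    return np.array([predict_one(tree, row) for row in X], dtype=int)


# ---------------------------------------------------------------------------
# rule extraction

def tree_to_rules(tree: DecisionTree) -> str:
    """Render the tree as a nested if/else rule string.

    A single-node tree over the repair-rank code prints exactly as
    ``if x1 = 3 then 1 else 0``.  Nested branches are parenthesised.
    """
    def walk(node: TreeNode) -> str:
        if node.is_leaf:
            return str(node.label)
        then_part = walk(node.match)
        else_part = walk(node.other)
        if not node.match.is_leaf:
            then_part = f"({then_part})"
        if not node.other.is_leaf:
            else_part = f"({else_part})"
        return (f"if {tree.name(node.feature)} = {node.value} "
                f"then {then_part} else {else_part}")
    return walk(tree.root)


_RULE_RE = re.compile(r"^if\s+(\S+)\s*=\s*(\S+)\s+then\s+", re.S)


def _parse_rule(text: str):
    """Recursive-descent parser for the rule grammar used above."""
    text = text.strip()
    if text.startswith("("):
        depth, pos = 0, 0
        for pos, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0:
                break
        inner, rest = text[1:pos], text[pos + 1:]
        node, leftover = _parse_rule(inner)
        if leftover.strip():
            raise ValueError("trailing text inside parentheses")
        return node, rest
    m = _RULE_RE.match(text)
    if m is None:
        lm = re.match(r"^(\d+)", text)
        if lm is None:
            raise ValueError(f"cannot parse rule near {text[:30]!r}")
        return ("leaf", int(lm.group(1))), text[lm.end():]
    name, value = m.group(1), m.group(2)
    then_node, rest = _parse_rule(text[m.end():])
    rest = rest.strip()
    if not rest.startswith("else"):
        raise ValueError("expected 'else'")
    else_node, rest = _parse_rule(rest[len("else"):])
    return ("if", name, value, then_node, else_node), rest


def evaluate_rules(rule_text: str, x, feature_names=None) -> int:
    """Evaluate a rule string against a sample; inverse of rule rendering.

    ``x`` is a mapping from feature name to value, or a sequence indexed
    by the default ``x1..xp`` names (or ``feature_names``).
    """
    if not isinstance(x, dict):
        seq = list(x)
        names = (list(feature_names) if feature_names
                 else [f"x{j + 1}" for j in range(len(seq))])
        x = dict(zip(names, seq))
    node, rest = _parse_rule(rule_text)
    if rest.strip():
        raise ValueError("trailing text after rule")

    def run(n):
        if n[0] == "leaf":
            return n[1]
        _, name, value, then_node, else_node = n
        if name not in x:
            raise ValueError(f"sample lacks feature {name!r}")
        return run(then_node) if str(x[name]) == value else run(else_node)
    return run(node)


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class ConfusionMetrics:
    """Pooled confusion counts and their derived ratios (positive = RA).

    Ratios with a zero denominator are ``nan`` and flagged in
    ``undefined``.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else float("nan")

    @property
    def undefined(self) -> list[str]:
        import math
        return [name for name in ("precision", "sensitivity",
                                  "specificity", "f1")
                if math.isnan(getattr(self, name))]

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "accuracy": self.accuracy, "precision": self.precision,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1}


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    return ConfusionMetrics(tp, fp, fn, tn)


def loocv(X, y, max_splits: int = 20,
          fit: Callable | None = None) -> ConfusionMetrics:
    """Leave-one-out cross-validation pooled into one confusion matrix.

    Each of the n refits omits one sample and predicts it; predictions
    are pooled with RA (class 1) as the positive class.  A custom ``fit``
    callable ``fit(X, y) -> tree`` overrides the default CART fit.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    if fit is None:
        def fit(Xt, yt):
            return fit_tree(Xt, yt, max_splits=max_splits)
    tp = fp = fn = tn = 0
    for i in range(n):
        keep = np.arange(n) != i
        tree = fit(X[keep], y[keep])
        pred = predict_one(tree, X[i])
        if y[i] == 1:
            tp += pred == 1
            fn += pred == 0
        else:
            tn += pred == 0
            fp += pred == 1
    return ConfusionMetrics(int(tp), int(fp), int(fn), int(tn))
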