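"""Feature selection around the decision-tree classifier.

Two wrapper searches — sequential forward selection (SFS) and sequential
backward selection (SBS) — greedily add or remove single features, each
candidate subset scored by the leave-one-out cross-validated accuracy of
the CART classifier.  Three model-free importance scorers complement
them: per-feature chi-square tests reported as ``-ln(p)``, a greedy
minimum-redundancy maximum-relevance (MRMR) ranking on plug-in mutual
information, and ReliefF weights from nearest-hit/nearest-miss value
differences under Hamming distance.  All features are categorical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import loocv


def dt_loocv_evaluator(max_splits: int = 20) -> Callable:
    """Evaluator ``(X, y) -> LOOCV accuracy`` wrapping the CART classifier."""
    def evaluate(X, y) -> float:
        return loocv(X, y, max_splits=max_splits).accuracy
    return evaluate


@dataclass(frozen=True)
class SelectionStep:
    step: int
    feature: int
    action: str          # "add" or "remove"
    subset: tuple[int, ...]
    accuracy: float


@dataclass
class SelectionTrace:
    """Ordered record of a greedy search; subsets are strictly nested."""

    method: str
    steps: list[SelectionStep] = field(default_factory=list)
    final_subset: tuple[int, ...] = ()
    final_accuracy: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "step": s.step, "action": s.action, "feature": s.feature,
            "subset": ",".join(str(j) for j in s.subset),
            "accuracy": s.accuracy,
        } for s in self.steps])


def sfs(X, y, evaluator: Callable | None = None,
        max_steps: int | None = None,
        run_to_exhaustion: bool = False) -> SelectionTrace:
    """Sequential forward selection.

    Starting from the empty set, each step adds the feature whose
    addition maximises the evaluator (ties -> lowest feature index) and
    stops when no addition strictly improves the score.  With
    ``run_to_exhaustion=True`` the search adds every feature and the
    final subset is the best ever seen.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    evaluator = evaluator or dt_loocv_evaluator()
    remaining = list(range(X.shape[1]))
    selected: list[int] = []
    trace = SelectionTrace(method="sfs")
    current = -math.inf
    best_seen: tuple[float, tuple[int, ...]] = (-math.inf, ())
    step = 0
    while remaining and (max_steps is None or step < max_steps):
        best_j, best_acc = None, -math.inf
        for j in remaining:
            acc = evaluator(X[:, sorted(selected + [j])], y)
            if acc > best_acc:
                best_j, best_acc = j, acc
        if not run_to_exhaustion and best_acc <= current:
            break
        step += 1
        selected.append(best_j)
        remaining.remove(best_j)
        current = best_acc
        subset = tuple(sorted(selected))
        trace.steps.append(SelectionStep(step, best_j, "add", subset, best_acc))
        if best_acc > best_seen[0]:
            best_seen = (best_acc, subset)
    if run_to_exhaustion:
        trace.final_accuracy, trace.final_subset = best_seen[0], best_seen[1]
    else:
        trace.final_subset = tuple(sorted(selected))
        trace.final_accuracy = current
    return trace


def sbs(X, y, evaluator: Callable | None = None,
        max_steps: int | None = None,
        run_to_exhaustion: bool = False) -> SelectionTrace:
    """Sequential backward selection.

    Starting from the full feature set, each step removes the feature
    whose removal yields the highest evaluator score (ties -> highest
    feature index removed) and continues while the score does not
    decrease.  With ``run_to_exhaustion=True`` elimination continues to a
    single feature and the best subset seen is returned.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 2:
        raise ValueError("backward selection needs >= 2 features")
    evaluator = evaluator or dt_loocv_evaluator()
    selected = list(range(X.shape[1]))
    current = evaluator(X, y)
    trace = SelectionTrace(method="sbs")
    trace.steps.append(SelectionStep(0, -1, "start",
                                     tuple(selected), current))
    best_seen = (current, tuple(selected))
    step = 0
    while len(selected) > 1 and (max_steps is None or step < max_steps):
        best_j, best_acc = None, -math.inf
        for j in sorted(selected, reverse=True):
            subset = [k for k in selected if k != j]
            acc = evaluator(X[:, subset], y)
            if acc > best_acc:
                best_j, best_acc = j, acc
        if not run_to_exhaustion and best_acc < current:
            break
        step += 1
        selected.remove(best_j)
        current = best_acc
        subset = tuple(selected)
        trace.steps.append(SelectionStep(step, best_j, "remove",
                                         subset, best_acc))
        if best_acc >= best_seen[0]:
            best_seen = (best_acc, subset)
    if run_to_exhaustion:
        trace.final_accuracy, trace.final_subset = best_seen
    else:
        trace.final_subset = tuple(selected)
        trace.final_accuracy = current
    return trace


# ---------------------------------------------------------------------------
# model-free importance scores

@dataclass
class FeatureScores:
    method: str
    scores: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    ranking: list[int] | None = None

    def to_frame(self) -> pd.DataFrame:
        names = (self.feature_names
                 or [f"x{j + 1}" for j in range(len(self.scores))])
        return pd.DataFrame({"feature": names, "score": self.scores})


def _contingency(column, y) -> np.ndarray:
    levels = _levels(column)
    classes = np.unique(y)
    table = np.zeros((len(levels), len(classes)))
    for i, v in enumerate(levels):
        for k, c in enumerate(classes):
            table[i, k] = np.sum((column == v) & (y == c))
    return table


def _levels(column) -> list:
    values = set(column.tolist())
    try:
        return sorted(values)
    except TypeError:
        return sorted(values, key=str)


def chi2_scores(X, y, feature_names: Sequence[str] | None = None
                ) -> FeatureScores:
    """Per-feature Pearson chi-square independence score ``-ln(p)``.

    Each feature is crossed with the class in a contingency table and
    tested without continuity correction; the score is the negative log
    p-value (computed via the survival function's log, so extremely small
    p do not underflow to infinity spuriously).  Constant features score
    0 with a warning.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        table = _contingency(X[:, j], y)
        r, c = table.shape
        if r < 2 or c < 2:
            warnings.warn(f"feature {j} is constant; chi2 score set to 0")
            continue
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(expected > 0,
                             (table - expected) ** 2 / expected, 0.0)
        statistic = float(terms.sum())
        dof = (r - 1) * (c - 1)
        scores[j] = float(-stats.chi2.logsf(statistic, dof))
    return FeatureScores("chi2", scores, list(feature_names or []))


def mutual_information(a, b) -> float:
    """Plug-in mutual information (natural log) of two categorical vectors."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    n = a.size
    mi = 0.0
    for va in _levels(a):
        mask_a = a == va
        pa = mask_a.sum() / n
        for vb in _levels(b):
            pab = np.sum(mask_a & (b == vb)) / n
            if pab > 0:
                pb = np.sum(b == vb) / n
                mi += pab * math.log(pab / (pa * pb))
    return max(mi, 0.0)


def entropy(a) -> float:
    """Plug-in Shannon entropy (nats) of a categorical vector."""
    a = np.asarray(a, dtype=object)
    n = a.size
    return -sum((c / n) * math.log(c / n)
                for c in (np.sum(a == v) for v in _levels(a)) if c > 0)


def mrmr_rank(X, y, feature_names: Sequence[str] | None = None
              ) -> FeatureScores:
    """Greedy MRMR ranking (mutual-information difference scheme).

    The first feature maximises relevance ``I(f; y)``; every subsequent
    pick maximises ``I(f; y) - mean over selected I(f; f_sel)``.  Scores
    record each feature's criterion value at the moment it was selected;
    ties break toward the lowest feature index.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=object)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")
    relevance = np.array([mutual_information(X[:, j], y) for j in range(p)])
    redundancy = np.zeros((p, p))
    computed = np.zeros((p, p), dtype=bool)

    def redun(i, j):
        if not computed[i, j]:
            redundancy[i, j] = redundancy[j, i] = \
                mutual_information(X[:, i], X[:, j])
            computed[i, j] = computed[j, i] = True
        return redundancy[i, j]

    ranking: list[int] = []
    scores = np.zeros(p)
    remaining = list(range(p))
    while remaining:
        best_j, best_val = None, -math.inf
        for j in remaining:
            if ranking:
                val = relevance[j] - np.mean([redun(j, s) for s in ranking])
            else:
                val = relevance[j]
            if val > best_val:
                best_j, best_val = j, val
        ranking.append(best_j)
        remaining.remove(best_j)
        scores[best_j] = best_val
    return FeatureScores("mrmr", scores, list(feature_names or []),
                         ranking=ranking)


def relieff_weights(X, y, k: int = 10, m: int | None = None,
                    seed: int | None = None,
                    feature_names: Sequence[str] | None = None
                    ) -> FeatureScores:
    """ReliefF weights for categorical features under Hamming distance.

    For each evaluated instance the k nearest same-class neighbours
    (hits) and k nearest other-class neighbours (misses) are found with
    ``diff(a, b) = 0`` if equal else 1 per feature; neighbour ties break
    toward the lower instance index.  Each feature's weight accumulates
    ``(mean miss diff - mean hit diff) / m`` — penalising features that
    differ between same-class neighbours and rewarding features that
    differ across classes — and therefore lies in [-1, 1].  By default
    every instance is evaluated (``m = n``, deterministic); a smaller
    ``m`` samples instances without replacement using ``seed``.
    """
    X = np.asarray(X, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n, p = X.shape
    class_sizes = {c: int(np.sum(y == c)) for c in np.unique(y)}
    if len(class_sizes) < 2:
        raise ValueError("ReliefF needs both classes present")
    min_size = min(class_sizes.values())
    if min_size < k + 1:
        k_eff = max(min_size - 1, 1)
        warnings.warn(f"class with {min_size} members: k reduced "
                      f"from {k} to {k_eff}")
        k = k_eff
    diff = (X[:, None, :] != X[None, :, :]).astype(float)  # n x n x p
    dist = diff.sum(axis=2)
    if m is None or m >= n:
        evaluated = np.arange(n)
    else:
        evaluated = np.sort(np.random.default_rng(seed).choice(
            n, size=m, replace=False))
    m_used = len(evaluated)
    weights = np.zeros(p)
    order_key = np.arange(n)
    for i in evaluated:
        same = (y == y[i]) & (order_key != i)
        other = y != y[i]
        for mask, sign in ((same, -1.0), (other, +1.0)):
            candidates = np.flatnonzero(mask)
            # nearest k by (distance, index)
            ordered = candidates[np.lexsort((candidates, dist[i, candidates]))]
            chosen = ordered[:k]
            weights += sign * diff[i, chosen, :].mean(axis=0) / m_used
    return FeatureScores("relieff", weights, list(feature_names or []))
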