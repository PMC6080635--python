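"""Conditional inference trees for a continuous response.

The base learner selects the split variable at each node with a
permutation-test linear association statistic rather than an impurity
criterion, which removes the selection bias toward predictors offering
many cutpoints.  For a candidate predictor ``x`` and node response ``y``
the raw statistic is

    T = sum_i x_i (y_i - ybar)

whose exact permutation moments (over random reassignments of ``y`` to
cases) are E[T] = 0 and

    Var[T] = n/(n-1) * mean((y - ybar)^2) * sum((x - xbar)^2).

The standardized score ``z = |T| / sqrt(Var[T])`` is referred to the
standard normal for a two-sided p-value.  The same statistic with the
left-child indicator in place of ``x`` scores candidate cutpoints.

Trees are grown unpruned by default (``alpha = 1``): with small samples
the ensemble, not individual-tree stopping, controls variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .errors import ConfigError
from ._rng import as_rng, spawn_rng

__all__ = [
    "CTreeParams",
    "CTreeNode",
    "linear_association_statistic",
    "select_split_variable",
    "best_binary_split",
    "fit_ctree",
    "predict_tree",
    "tree_to_dict",
    "tree_from_dict",
]

# variances below this are treated as degenerate (constant column / response)
_VAR_TOL = 1e-12


@dataclass
class CTreeParams:
    """Hyperparameters of a single conditional inference tree.

    mtry        candidate predictors drawn (without replacement) per node
    min_split   smallest node size at which a split is attempted
    min_bucket  smallest admissible child size
    alpha       stop when the Bonferroni-adjusted minimum candidate
                p-value exceeds alpha; 1.0 disables test-based stopping
    max_depth   hard depth cap; None means unlimited
    """

    mtry: int = 4
    min_split: int = 8
    min_bucket: int = 3
    alpha: float = 1.0
    max_depth: int | None = None

    def validate(self, n_features: int | None = None) -> None:
        if self.mtry < 1:
            raise ConfigError(f"mtry must be >= 1, got {self.mtry}")
        if n_features is not None and self.mtry > n_features:
            # mtry is silently capped at p during fitting; only reject nonsense
            pass
        if self.min_bucket < 1:
            raise ConfigError(f"min_bucket must be >= 1, got {self.min_bucket}")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigError(f"max_depth must be >= 0, got {self.max_depth}")


@dataclass
class CTreeNode:
    """A node of a fitted tree.

    Terminal nodes carry the mean response of their training cases.
    Internal nodes route cases with ``x[split_var] <= threshold`` to the
    left child (the tie convention: values equal to the threshold go left).
    """

    n: int
    prediction: float
    split_var: int | None = None
    threshold: float | None = None
    left: "CTreeNode | None" = None
    right: "CTreeNode | None" = None
    # set on the root only, for layout validation at predict time
    n_features: int | None = field(default=None, repr=False)

    @property
    def is_terminal(self) -> bool:
        return self.split_var is None

    def depth(self) -> int:
        if self.is_terminal:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def split_variables(self) -> set[int]:
        """Indices of every predictor used in some internal node."""
        if self.is_terminal:
            return set()
        return {self.split_var} | self.left.split_variables() | self.right.split_variables()


def _assoc_scores(Xc: np.ndarray, h: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized association z-scores/p-values for candidate columns.

    ``h`` must already be centered.  Returns (z, p, degenerate) where
    degenerate marks columns with zero variance (or constant response).
    """
    T = h @ Xc
    colsum = Xc.sum(axis=0)
    ssx = (Xc * Xc).sum(axis=0) - colsum * colsum / n
    mh2 = float(h @ h) / n
    degenerate = (ssx <= _VAR_TOL) | (mh2 <= _VAR_TOL)
    var = (n / (n - 1)) * mh2 * ssx
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(T) / np.sqrt(var)
    z = np.where(degenerate, 0.0, z)
    p = np.where(degenerate, 1.0, 2.0 * ndtr(-z))
    return z, p, degenerate


def linear_association_statistic(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Standardized linear association score and two-sided asymptotic p-value.

    Degenerate inputs (constant ``x`` or constant ``y``) give ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("x and y must be one-dimensional")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    h = y - y.mean()
    z, p, _ = _assoc_scores(x[:, None], h, n)
    return float(z[0]), float(p[0])


def select_split_variable(
    X: np.ndarray, y: np.ndarray, candidate_idx: Sequence[int]
) -> tuple[int, dict[int, float]]:
    """Pick the candidate with the smallest association p-value.

    Ties break toward the smallest column index.  Returns the chosen
    index and the per-candidate p-values for diagnostics.
    """
    candidates = np.asarray(sorted(candidate_idx), dtype=int)
    if candidates.size == 0:
        raise ValueError("candidate set is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    h = y - y.mean()
    _, p, _ = _assoc_scores(X[:, candidates], h, y.shape[0])
    chosen = int(candidates[int(np.argmin(p))])  # argmin: first minimum = smallest index
    return chosen, {int(j): float(pj) for j, pj in zip(candidates, p)}


def best_binary_split(
    x: Sequence[float], y: Sequence[float], min_bucket: int = 1
) -> tuple[float, float] | None:
    """Best cutpoint for one predictor by the standardized two-sample statistic.

    Every midpoint between consecutive distinct ``x`` values whose children
    both hold at least ``min_bucket`` cases is scored; the cutpoint with
    the largest standardized mean-difference statistic wins, the smallest
    threshold breaking ties.  Returns ``(threshold, statistic)`` or ``None``
    when no cutpoint is admissible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    h = y - y.mean()
    hs = h[order]
    k = np.arange(1, n)  # candidate left-child sizes
    at_boundary = xs[1:] > xs[:-1]
    admissible = at_boundary & (k >= min_bucket) & ((n - k) >= min_bucket)
    if not admissible.any():
        return None
    mh2 = float(h @ h) / n
    left_sums = np.cumsum(hs)[:-1]
    if mh2 <= _VAR_TOL:
        z = np.zeros(n - 1)
    else:
        var = (n / (n - 1)) * mh2 * k * (n - k) / n
        z = np.abs(left_sums) / np.sqrt(var)
    z = np.where(admissible, z, -np.inf)
    kbest = int(np.argmax(z))  # first maximum = smallest threshold on ties
    threshold = float((xs[kbest] + xs[kbest + 1]) / 2.0)
    return threshold, float(z[kbest])


def fit_ctree(
    X: np.ndarray,
    y: np.ndarray,
    params: CTreeParams | None = None,
    rng_state: int | np.random.Generator | None = None,
) -> CTreeNode:
    """Grow a conditional inference tree.

    Recursion stops when a node is smaller than ``min_split``, hits
    ``max_depth``, has a (near-)constant response, offers no admissible
    cutpoint, or — when ``alpha < 1`` — when the Bonferroni-adjusted
    minimum candidate p-value exceeds ``alpha``.  Candidate predictors are
    drawn fresh at every node, so the fit is deterministic given
    ``rng_state``.
    """
    params = params or CTreeParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 1:
        raise ValueError("need at least one case")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    params.validate(X.shape[1])
    rng = as_rng(rng_state)
    # candidate draws are keyed to the node's path in the tree (root = 1,
    # children 2k / 2k+1) off one base seed: pruning a branch never shifts
    # the randomness seen by any other node
    base_seed = int(rng.integers(1 << 31))
    root = _grow(X, y, np.arange(X.shape[0]), params, base_seed, depth=0, path=1)
    root.n_features = X.shape[1]
    return root


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    params: CTreeParams,
    base_seed: int,
    depth: int,
    path: int,
) -> CTreeNode:
    n = idx.shape[0]
    y_node = y[idx]
    node = CTreeNode(n=n, prediction=float(y_node.mean()))
    if n < params.min_split or n < 2 * params.min_bucket:
        return node
    if params.max_depth is not None and depth >= params.max_depth:
        return node
    h = y_node - y_node.mean()
    if float(h @ h) / n <= _VAR_TOL:
        return node

    p_total = X.shape[1]
    m = min(params.mtry, p_total)
    node_rng = spawn_rng(base_seed, path)
    candidates = np.sort(node_rng.choice(p_total, size=m, replace=False))
    Xc = X[np.ix_(idx, candidates)]
    _, pvals, degenerate = _assoc_scores(Xc, h, n)
    if degenerate.all():
        return node
    pvals = np.where(degenerate, np.inf, pvals)  # never select a constant column
    if params.alpha < 1.0:
        p_adj = min(1.0, float(np.min(pvals)) * m)
        if p_adj > params.alpha:
            return node
    chosen_pos = int(np.argmin(pvals))
    chosen = int(candidates[chosen_pos])

    split = best_binary_split(X[idx, chosen], y_node, params.min_bucket)
    if split is None:
        return node
    threshold, _ = split
    go_left = X[idx, chosen] <= threshold
    node.split_var = chosen
    node.threshold = threshold
    node.left = _grow(X, y, idx[go_left], params, base_seed, depth + 1, 2 * path)
    node.right = _grow(X, y, idx[~go_left], params, base_seed, depth + 1, 2 * path + 1)
    return node


def predict_tree(tree: CTreeNode, X: np.ndarray) -> np.ndarray:
    """Route each row of ``X`` to a terminal node and return its prediction."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    needed = tree.n_features if tree.n_features is not None else (
        max(tree.split_variables(), default=-1) + 1
    )
    if X.shape[1] < needed:
        raise ValueError(f"X has {X.shape[1]} columns; tree expects at least {needed}")
    out = np.empty(X.shape[0], dtype=float)
    _route(tree, X, np.arange(X.shape[0]), out)
    return out


def _route(node: CTreeNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_terminal:
        out[idx] = node.prediction
        return
    go_left = X[idx, node.split_var] <= node.threshold
    _route(node.left, X, idx[go_left], out)
    _route(node.right, X, idx[~go_left], out)


def tree_to_dict(node: CTreeNode, feature_names: Sequence[str] | None = None) -> dict:
    """JSON-serializable nested record of a fitted tree."""
    if node.is_terminal:
        return {"n": node.n, "prediction": node.prediction}
    rec = {
        "n": node.n,
        "prediction": node.prediction,
        "split_var": int(node.split_var),
        "threshold": float(node.threshold),
        "left": tree_to_dict(node.left, feature_names),
        "right": tree_to_dict(node.right, feature_names),
    }
    if feature_names is not None:
        rec["split_name"] = str(feature_names[node.split_var])
    return rec


def tree_from_dict(rec: dict) -> CTreeNode:
    if "split_var" not in rec:
        return CTreeNode(n=int(rec["n"]), prediction=float(rec["prediction"]))
    return CTreeNode(
        n=int(rec["n"]),
        prediction=float(rec["prediction"]),
        split_var=int(rec["split_var"]),
        threshold=float(rec["threshold"]),
        left=tree_from_dict(rec["left"]),
        right=tree_from_dict(rec["right"]),
    )


def tree_to_json(node: CTreeNode, feature_names: Sequence[str] | None = None) -> str:
    return json.dumps(tree_to_dict(node, feature_names), sort_keys=True)


def tree_from_json(text: str) -> CTreeNode:
    return tree_from_dict(json.loads(text))
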