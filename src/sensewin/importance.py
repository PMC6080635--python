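"""Permutation variable importance on the out-of-bag cases.

Importance of predictor ``j`` is the increase in a tree's OOB mean
squared error after permuting column ``j`` among that tree's OOB cases,
averaged over trees.  Permuting destroys the predictor's association
with the response while leaving its marginal distribution intact, so a
large MSE increase marks a predictor the forest actually relied on;
permuting an unimportant predictor leaves the fit essentially unchanged.
Trees that never split on ``j`` are invariant to the permutation and
contribute exactly 0.  Negative values (sampling noise) are reported
as-is, not truncated.

Within one tree and permutation replicate the same permutation of OOB
positions is applied to whichever column is being scored.  This common
random numbers scheme makes the profile exactly invariant to predictor
column order and reduces between-predictor Monte-Carlo variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cforest import Forest
from .ctree import predict_tree
from ._rng import spawn_rng

__all__ = ["ImportanceProfile", "permutation_importance"]


@dataclass
class ImportanceProfile:
    """Per-predictor mean OOB MSE increase with per-tree detail."""

    names: list[str]
    categories: list[str]
    importance: np.ndarray  # (p,) mean over trees
    per_tree_values: np.ndarray  # (n_trees, p)
    n_permutations: int
    seed: int

    def se(self) -> np.ndarray:
        """Standard error of the mean over trees."""
        n_trees = self.per_tree_values.shape[0]
        return self.per_tree_values.std(axis=0, ddof=1) / np.sqrt(n_trees)

    def rank(self) -> np.ndarray:
        """1 = most important."""
        order = np.argsort(-self.importance, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.names,
                "category": self.categories,
                "importance": self.importance,
                "se": self.se(),
                "rank": self.rank(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def permutation_importance(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    predictors: Sequence[int] | None = None,
    n_perm: int = 1,
    rng_state: int = 0,
    names: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
) -> ImportanceProfile:
    """Mean OOB MSE increase per predictor.

    ``predictors`` restricts the profile to a subset of columns (default
    all).  ``n_perm`` independent permutations per tree are averaged;
    the default 1 relies on the ensemble to absorb permutation noise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    predictors = (
        np.arange(X.shape[1], dtype=int)
        if predictors is None
        else np.asarray(predictors, dtype=int)
    )
    p_sel = predictors.shape[0]
    n_trees = len(forest.trees)
    per_tree = np.zeros((n_trees, p_sel))
    pos_of = {int(j): pos for pos, j in enumerate(predictors)}

    for t, tree in enumerate(forest.trees):
        oob_idx = forest.oob_indices(t)
        if oob_idx.size == 0:
            continue
        Xo = X[oob_idx].copy()
        yo = y[oob_idx]
        base = predict_tree(tree, Xo)
        base_mse = float(np.mean((yo - base) ** 2))
        used = tree.split_variables() & pos_of.keys()
        if not used:
            continue
        rng = spawn_rng(rng_state, t)
        # one shared permutation per replicate, applied to every scored column
        perms = [rng.permutation(oob_idx.size) for _ in range(n_perm)]
        for j in sorted(used):
            saved = Xo[:, j].copy()
            mse_sum = 0.0
            for perm in perms:
                Xo[:, j] = saved[perm]
                pred = predict_tree(tree, Xo)
                mse_sum += float(np.mean((yo - pred) ** 2))
            Xo[:, j] = saved
            per_tree[t, pos_of[j]] = mse_sum / n_perm - base_mse

    if names is None:
        if forest.predictor_names is not None:
            names = [forest.predictor_names[j] for j in predictors]
        else:
            names = [f"x{j}" for j in predictors]
    if categories is None:
        categories = ["predictor"] * p_sel
    return ImportanceProfile(
        names=list(names),
        categories=list(categories),
        importance=per_tree.mean(axis=0),
        per_tree_values=per_tree,
        n_permutations=n_perm,
        seed=rng_state,
    )
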