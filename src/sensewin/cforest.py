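"""Ensembles of conditional inference trees.

Each tree is grown on a without-replacement subsample (default fraction
0.632) of the cases, drawing fresh split-variable candidates at every
node.  Predictions aggregate as the unweighted mean over trees; cases are
evaluated out-of-bag (OOB) only by trees whose subsample excluded them,
which gives an honest estimate of prediction error on small cohorts.

Per-tree random streams are split off the forest seed as
``SeedSequence(entropy=seed, spawn_key=(tree_index,))`` so a fitted
forest is reproducible across platforms from its config alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ctree import (
    CTreeNode,
    CTreeParams,
    fit_ctree,
    predict_tree,
    tree_from_dict,
    tree_to_dict,
)
from .errors import ConfigError
from ._rng import spawn_rng

__all__ = ["ForestConfig", "Forest", "fit_forest", "predict_forest", "oob_mse"]


@dataclass
class ForestConfig:
    """Forest hyperparameters.

    The defaults (200 trees, 4 candidate variables per node, unpruned
    trees) are the settings this analysis is normally run with; the
    subsampling fraction 0.632 without replacement follows the usual
    conditional-forest convention.
    """

    n_trees: int = 200
    mtry: int = 4
    subsample_fraction: float = 0.632
    tree_params: CTreeParams = field(default_factory=CTreeParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigError(f"n_trees must be >= 1, got {self.n_trees}")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ConfigError(
                f"subsample_fraction must be in (0, 1], got {self.subsample_fraction}"
            )
        self.tree_params.validate()

    def to_dict(self) -> dict:
        tp = self.tree_params
        return {
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "subsample_fraction": self.subsample_fraction,
            "tree_params": {
                "mtry": tp.mtry,
                "min_split": tp.min_split,
                "min_bucket": tp.min_bucket,
                "alpha": tp.alpha,
                "max_depth": tp.max_depth,
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "ForestConfig":
        tp = rec.get("tree_params", {})
        return cls(
            n_trees=int(rec["n_trees"]),
            mtry=int(rec["mtry"]),
            subsample_fraction=float(rec["subsample_fraction"]),
            tree_params=CTreeParams(
                mtry=int(tp.get("mtry", rec["mtry"])),
                min_split=int(tp.get("min_split", 8)),
                min_bucket=int(tp.get("min_bucket", 3)),
                alpha=float(tp.get("alpha", 1.0)),
                max_depth=tp.get("max_depth"),
            ),
            seed=int(rec["seed"]),
        )


@dataclass
class Forest:
    """A fitted ensemble with its in-bag bookkeeping."""

    trees: list[CTreeNode]
    in_bag: list[np.ndarray]  # per-tree sorted training indices
    config: ForestConfig
    n_train: int
    predictor_names: list[str] | None = None

    def oob_indices(self, t: int) -> np.ndarray:
        mask = np.ones(self.n_train, dtype=bool)
        mask[self.in_bag[t]] = False
        return np.nonzero(mask)[0]

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "n_train": self.n_train,
            "predictor_names": self.predictor_names,
            "in_bag": [bag.tolist() for bag in self.in_bag],
            "trees": [tree_to_dict(t, self.predictor_names) for t in self.trees],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Forest":
        payload = json.loads(text)
        trees = [tree_from_dict(rec) for rec in payload["trees"]]
        names = payload.get("predictor_names")
        n_features = None if names is None else len(names)
        for tree in trees:
            tree.n_features = n_features
        return cls(
            trees=trees,
            in_bag=[np.asarray(bag, dtype=int) for bag in payload["in_bag"]],
            config=ForestConfig.from_dict(payload["config"]),
            n_train=int(payload["n_train"]),
            predictor_names=names,
        )


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig | None = None,
    predictor_names: Sequence[str] | None = None,
) -> Forest:
    """Fit ``config.n_trees`` conditional trees on without-replacement subsamples."""
    config = config or ForestConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 cases to fit a forest, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    n_bag = max(1, int(round(config.subsample_fraction * n)))
    tree_params = replace(config.tree_params, mtry=config.mtry)
    if n_bag < tree_params.min_split:
        warnings.warn(
            f"subsample size {n_bag} is below min_split {tree_params.min_split}; "
            "trees will be root-only",
            stacklevel=2,
        )
    trees: list[CTreeNode] = []
    in_bag: list[np.ndarray] = []
    for t in range(config.n_trees):
        rng = spawn_rng(config.seed, t)
        bag = np.sort(rng.choice(n, size=n_bag, replace=False))
        tree = fit_ctree(X[bag], y[bag], tree_params, rng)
        tree.n_features = X.shape[1]
        trees.append(tree)
        in_bag.append(bag)
    return Forest(
        trees=trees,
        in_bag=in_bag,
        config=config,
        n_train=n,
        predictor_names=list(predictor_names) if predictor_names is not None else None,
    )


def predict_forest(forest: Forest, X: np.ndarray, oob: bool = False) -> np.ndarray:
    """Unweighted mean of tree predictions.

    With ``oob=True``, ``X`` must be the training matrix: case ``i`` is
    predicted only by trees whose subsample excluded it, and a case that
    is in-bag for every tree gets ``nan``.
    """
    X = np.asarray(X, dtype=float)
    if not oob:
        acc = np.zeros(X.shape[0])
        for tree in forest.trees:
            acc += predict_tree(tree, X)
        return acc / len(forest.trees)
    if X.shape[0] != forest.n_train:
        raise ValueError(
            "OOB prediction requires the training matrix "
            f"({forest.n_train} rows, got {X.shape[0]})"
        )
    sums = np.zeros(forest.n_train)
    counts = np.zeros(forest.n_train)
    for t, tree in enumerate(forest.trees):
        oob_idx = forest.oob_indices(t)
        if oob_idx.size == 0:
            continue
        sums[oob_idx] += predict_tree(tree, X[oob_idx])
        counts[oob_idx] += 1
    with np.errstate(invalid="ignore"):
        preds = sums / counts
    preds[counts == 0] = np.nan
    return preds


def oob_mse(forest: Forest, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of OOB predictions over cases with >= 1 OOB tree."""
    y = np.asarray(y, dtype=float)
    preds = predict_forest(forest, X, oob=True)
    valid = ~np.isnan(preds)
    if not valid.any():
        raise ValueError("no case has an out-of-bag prediction")
    resid = y[valid] - preds[valid]
    return float(np.mean(resid * resid))
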