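"""Re-randomization significance tests for permutation importance.

The observed importance profile has no closed-form null distribution, so
significance is assessed by refitting the entire forest ``B`` times on
response vectors reshuffled across subjects.  Permuting the response
breaks every response-predictor association at once while leaving the
(correlated) predictor matrix intact, so the null preserves the
inter-predictor dependence structure of the exposure histories.

Three tests are built from the same ``B x p`` null matrix:

* max-importance: the peak importance over a predictor set against the
  null distribution of the same maximum (a max-statistic test, immune to
  selection of the peak);
* per-predictor: marginal add-one permutation p-values, with
  Benjamini-Hochberg FDR adjustment across the family;
* combined-window: the summed importance of a contiguous block of age
  bins against the null maximum over all same-length windows, which
  accounts for the window having been chosen at the observed peak.

All p-values use the add-one estimator (1 + #{null >= observed})/(B + 1),
which is valid (conservative) at any ``B``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cforest import Forest, ForestConfig, fit_forest
from .importance import ImportanceProfile, permutation_importance
from ._rng import derive_seed, spawn_rng

__all__ = [
    "RerandResult",
    "rerandomization_null",
    "max_importance_test",
    "per_predictor_pvalues",
    "bh_fdr",
    "combined_window_test",
]


@dataclass
class RerandResult:
    """Observed importances with their re-randomization null and p-values."""

    observed: ImportanceProfile
    null_matrix: np.ndarray  # (B, p) null importance profiles
    max_set: np.ndarray  # positions (into observed) over which the max is taken
    p_max: float
    p_per_predictor: np.ndarray
    q_per_predictor: np.ndarray
    B: int
    seed: int
    combined: dict | None = None  # {"window": positions, "statistic": s, "p": p}


def rerandomization_null(
    X: np.ndarray,
    y: np.ndarray,
    predictors: Sequence[int],
    forest_config: ForestConfig,
    B: int,
    rng_state: int = 0,
    n_perm: int = 1,
) -> np.ndarray:
    """``B`` importance profiles from forests refit on reshuffled responses.

    Replicate ``b`` draws its permutation and derived forest seed from
    stream ``(rng_state, b)``, so the null matrix is reproducible and
    rows are exchangeable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    predictors = np.asarray(predictors, dtype=int)
    null = np.empty((B, predictors.shape[0]))
    for b in range(B):
        rng = spawn_rng(rng_state, b)
        y_perm = y[rng.permutation(y.shape[0])]
        cfg = replace(forest_config, seed=derive_seed(rng_state, b, 1))
        forest = fit_forest(X, y_perm, cfg)
        prof = permutation_importance(
            forest, X, y_perm, predictors=predictors, n_perm=n_perm,
            rng_state=derive_seed(rng_state, b, 2),
        )
        null[b] = prof.importance
    return null


def max_importance_test(
    observed: np.ndarray, null_matrix: np.ndarray, predictors: Sequence[int] | None = None
) -> float:
    """Add-one p-value for the maximal observed importance over a predictor set.

    ``predictors`` are positions into the profile; the null maximum is
    taken over the same positions row-wise.
    """
    observed = np.asarray(observed, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.size == 0:
        raise ValueError("null matrix is empty")
    pos = (
        np.arange(observed.shape[0])
        if predictors is None
        else np.asarray(predictors, dtype=int)
    )
    if pos.size == 0:
        raise ValueError("predictor set is empty")
    stat = float(observed[pos].max())
    null_max = null_matrix[:, pos].max(axis=1)
    B = null_matrix.shape[0]
    return float((1 + int((null_max >= stat).sum())) / (B + 1))


def per_predictor_pvalues(observed: np.ndarray, null_matrix: np.ndarray) -> np.ndarray:
    """Marginal add-one p-values, one per profile position."""
    observed = np.asarray(observed, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    B = null_matrix.shape[0]
    exceed = (null_matrix >= observed[None, :]).sum(axis=0)
    return (1 + exceed) / (B + 1)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def combined_window_test(
    observed: np.ndarray, null_matrix: np.ndarray, window: Sequence[int]
) -> dict:
    """Summed importance of a contiguous window vs. the null max over windows.

    ``window`` holds contiguous positions into the profile, whose columns
    must be ordered by age.  The null statistic in each row is the
    maximum over every contiguous window of the same length, so the test
    pays for the window having been selected at the observed peak.
    """
    observed = np.asarray(observed, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    window = np.asarray(sorted(window), dtype=int)
    if window.size == 0:
        raise ValueError("window is empty")
    if not np.all(np.diff(window) == 1):
        raise ValueError(f"window positions must be contiguous, got {window.tolist()}")
    if window[0] < 0 or window[-1] >= observed.shape[0]:
        raise ValueError("window positions out of range")
    w = window.size
    stat = float(observed[window].sum())
    kernel = np.ones(w)
    # row-wise sums of every length-w contiguous window
    null_best = np.array(
        [np.convolve(row, kernel, mode="valid").max() for row in null_matrix]
    )
    B = null_matrix.shape[0]
    p = float((1 + int((null_best >= stat).sum())) / (B + 1))
    return {"window": window.tolist(), "statistic": stat, "p": p}


def rerandomization_test(
    X: np.ndarray,
    y: np.ndarray,
    observed: ImportanceProfile,
    predictors: Sequence[int],
    max_set: Sequence[int],
    forest_config: ForestConfig,
    B: int,
    rng_state: int = 0,
    window: Sequence[int] | None = None,
    n_perm: int = 1,
) -> RerandResult:
    """Full machinery: null matrix, max-statistic p, per-predictor p/q, window test.

    ``predictors`` are the profile's column indices into ``X``;
    ``max_set`` and ``window`` are positions into the profile (i.e. into
    ``predictors``), restricting the max statistic and the combined test
    to, say, the age-bin block.
    """
    predictors = np.asarray(predictors, dtype=int)
    null = rerandomization_null(X, y, predictors, forest_config, B, rng_state, n_perm)
    max_set = np.asarray(max_set, dtype=int)
    p_max = max_importance_test(observed.importance, null, max_set)
    p_vec = per_predictor_pvalues(observed.importance, null)
    q_vec = np.full_like(p_vec, np.nan)
    q_vec[max_set] = bh_fdr(p_vec[max_set])  # FDR family = the tested set
    combined = None
    if window is not None:
        # slide the null windows over the tested block only (e.g. age bins),
        # never across unrelated columns such as duration or prenatal flags
        window = np.asarray(sorted(window), dtype=int)
        pos_in_block = np.searchsorted(max_set, window)
        if pos_in_block.max(initial=-1) >= max_set.size or not np.all(
            max_set[pos_in_block] == window
        ):
            raise ValueError("combined window must lie within the tested predictor set")
        combined = combined_window_test(
            observed.importance[max_set], null[:, max_set], pos_in_block
        )
        combined["window"] = window.tolist()
    return RerandResult(
        observed=observed,
        null_matrix=null,
        max_set=max_set,
        p_max=p_max,
        p_per_predictor=p_vec,
        q_per_predictor=q_vec,
        B=B,
        seed=rng_state,
        combined=combined,
    )
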