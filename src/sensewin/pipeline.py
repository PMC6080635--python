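"""End-to-end sensitive-period analyses on cohort tables.

Three designs are supported, all regressing a continuous regional
signal on exposure predictors with a conditional-inference forest:

* timing  — prenatal flag + one 0/1 predictor per year of life +
            exposure duration; the max-importance statistic and the FDR
            family are the age bins ("at any age"), with duration and
            the prenatal flag as controls in the fit.
* type    — four maltreatment-type indicators + number of types; the
            statistic is taken over all five predictors.
* symptom — the timing design rerun once per symptom subscale response,
            FDR-corrected within each subscale.

The response is first centered and scaled to mean 100 / SD 10 (an
arbitrary but conventional scale for regional eigenvariate scores).
Reported ``prediction_r`` is the Pearson correlation between
out-of-bag forest predictions and the actual (scaled) response, which
avoids the optimistic in-sample correlation of a forest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cforest import ForestConfig, fit_forest, oob_mse, predict_forest
from .cohort_sim import TSCC_SUBSCALES, CohortTable
from .errors import SchemaError
from .importance import ImportanceProfile, permutation_importance
from .rerand import RerandResult, rerandomization_test
from ._rng import derive_seed

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "scale_signal",
    "cluster_eigenvariate",
    "run_timing_analysis",
    "run_type_analysis",
    "run_symptom_analysis",
]


def scale_signal(values: Sequence[float]) -> np.ndarray:
    """Center and scale to sample mean 100 and sample SD 10 (ddof=1).

    Idempotent: a vector already on this scale is returned unchanged (up
    to float tolerance).  Constant input has no defined scale and raises.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape[0] < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot scale a constant vector (zero SD)")
    return (v - v.mean()) / sd * 10.0 + 100.0


def cluster_eigenvariate(voxel_matrix: np.ndarray) -> np.ndarray:
    """First-singular-vector summary of a subjects x voxels cluster matrix.

    Columns (voxels) are mean-centered; the output is the first left
    singular vector scaled by its singular value — the dominant shared
    signal across the cluster, one value per subject.  Its sign is fixed
    so that it correlates positively with the subject-wise mean of the
    centered matrix.
    """
    M = np.asarray(voxel_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 1 voxel")
    if np.isnan(M).any():
        raise ValueError("missing values are not supported")
    C = M - M.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("cluster matrix has rank 0 after centering")
    ev = U[:, 0] * s[0]
    if ev @ C.mean(axis=1) < 0:
        ev = -ev
    return ev


@dataclass
class RunConfig:
    """Settings for one analysis run.

    ``n_rerand`` (B) defaults to 10,000 reshuffled forests; simulations
    and interactive runs typically lower it.  ``window`` names age bins
    (by bin index) for the optional combined-window test.
    """

    forest: ForestConfig = field(default_factory=ForestConfig)
    n_rerand: int = 10_000
    window: tuple[int, ...] | None = None
    n_perm: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "forest": self.forest.to_dict(),
            "n_rerand": self.n_rerand,
            "window": list(self.window) if self.window is not None else None,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "RunConfig":
        return cls(
            forest=ForestConfig.from_dict(rec["forest"]),
            n_rerand=int(rec["n_rerand"]),
            window=tuple(rec["window"]) if rec.get("window") is not None else None,
            n_perm=int(rec.get("n_perm", 1)),
            seed=int(rec["seed"]),
        )


@dataclass
class AnalysisReport:
    """Everything one analysis produced, re-runnable from its own snapshot."""

    design: str
    response_name: str
    importance: ImportanceProfile
    rerand: RerandResult
    prediction_r: float
    oob_mse: float
    config: RunConfig
    seed: int

    def to_dict(self) -> dict:
        prof = self.importance
        null = self.rerand.null_matrix
        qtl = np.quantile(null, [0.025, 0.5, 0.975], axis=0)
        table = []
        ranks = prof.rank()
        se = prof.se()
        for i, name in enumerate(prof.names):
            table.append(
                {
                    "predictor": name,
                    "category": prof.categories[i],
                    "importance": float(prof.importance[i]),
                    "se": float(se[i]),
                    "rank": int(ranks[i]),
                    "p": float(self.rerand.p_per_predictor[i]),
                    "q": (
                        None
                        if np.isnan(self.rerand.q_per_predictor[i])
                        else float(self.rerand.q_per_predictor[i])
                    ),
                    "null_q025": float(qtl[0, i]),
                    "null_median": float(qtl[1, i]),
                    "null_q975": float(qtl[2, i]),
                }
            )
        return {
            "design": self.design,
            "response": self.response_name,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "prediction_r": self.prediction_r,
            "oob_mse": self.oob_mse,
            "p_max": self.rerand.p_max,
            "max_set": [prof.names[i] for i in self.rerand.max_set],
            "combined": self.rerand.combined,
            "importance": table,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _run_design(
    cohort: CohortTable,
    response_name: str,
    columns: list[str],
    max_columns: list[str],
    design: str,
    run_config: RunConfig,
) -> AnalysisReport:
    X, names, categories = cohort.design(columns)
    if np.isnan(X).any():
        raise SchemaError("cohort predictors contain missing values")
    y = scale_signal(cohort.response(response_name))
    seed = run_config.seed
    fc = ForestConfig.from_dict(run_config.forest.to_dict())
    fc.seed = derive_seed(seed, 0)
    forest = fit_forest(X, y, fc, predictor_names=names)
    observed = permutation_importance(
        forest,
        X,
        y,
        n_perm=run_config.n_perm,
        rng_state=derive_seed(seed, 1),
        names=names,
        categories=categories,
    )
    max_set = [names.index(c) for c in max_columns]
    window = None
    if run_config.window is not None:
        bin_cols = [cohort.age_columns[a] for a in run_config.window]
        missing = [c for c in bin_cols if c not in names]
        if missing:
            raise SchemaError(f"combined-window bins not in design: {missing}")
        window = [names.index(c) for c in bin_cols]
    rerand = rerandomization_test(
        X,
        y,
        observed,
        predictors=np.arange(X.shape[1]),
        max_set=max_set,
        forest_config=fc,
        B=run_config.n_rerand,
        rng_state=derive_seed(seed, 2),
        window=window,
        n_perm=run_config.n_perm,
    )
    oob_pred = predict_forest(forest, X, oob=True)
    valid = ~np.isnan(oob_pred)
    prediction_r = float(np.corrcoef(oob_pred[valid], y[valid])[0, 1])
    return AnalysisReport(
        design=design,
        response_name=response_name,
        importance=observed,
        rerand=rerand,
        prediction_r=prediction_r,
        oob_mse=oob_mse(forest, X, y),
        config=run_config,
        seed=seed,
    )


def run_timing_analysis(
    cohort: CohortTable, response_name: str = "gm_signal", run_config: RunConfig | None = None
) -> AnalysisReport:
    """When did exposure matter?  Annual bins + prenatal flag + duration.

    The max-importance statistic, the per-age p-values and the FDR
    family cover the age bins only; duration and the prenatal flag
    control for confounding between early onset and long exposure.
    """
    run_config = run_config or RunConfig()
    return _run_design(
        cohort,
        response_name,
        columns=cohort.timing_columns,
        max_columns=cohort.age_columns,
        design="timing",
        run_config=run_config,
    )


def run_type_analysis(
    cohort: CohortTable, response_name: str = "gm_signal", run_config: RunConfig | None = None
) -> AnalysisReport:
    """Which kind of exposure mattered?  Four types + number of types."""
    run_config = run_config or RunConfig()
    if run_config.window is not None:
        raise ValueError("combined-window test applies to the timing design only")
    return _run_design(
        cohort,
        response_name,
        columns=cohort.type_columns,
        max_columns=cohort.type_columns,
        design="type",
        run_config=run_config,
    )


def run_symptom_analysis(
    cohort: CohortTable,
    subscale_names: Sequence[str] = TSCC_SUBSCALES,
    run_config: RunConfig | None = None,
) -> dict[str, AnalysisReport]:
    """Timing design rerun per symptom subscale, FDR within each subscale.

    Missing subscale columns are skipped with a warning rather than
    failing the whole batch.
    """
    run_config = run_config or RunConfig()
    reports: dict[str, AnalysisReport] = {}
    for s, name in enumerate(subscale_names):
        if name not in cohort.frame.columns:
            warnings.warn(f"subscale {name!r} absent from cohort; skipped", stacklevel=2)
            continue
        sub_cfg = RunConfig.from_dict(run_config.to_dict())
        sub_cfg.seed = derive_seed(run_config.seed, 100 + s)
        reports[name] = _run_design(
            cohort,
            name,
            columns=cohort.timing_columns,
            max_columns=cohort.age_columns,
            design="symptom",
            run_config=sub_cfg,
        )
    return reports
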