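"""Synthetic maltreatment-exposure cohorts.

The generator emulates the structure of a small clinical cohort of
maltreated children: each subject has a prenatal domestic-violence flag,
a 0/1 exposure indicator for each year of life (any maltreatment during
year ``[a, a+1)``), indicators for four maltreatment types (physical,
emotional, sexual abuse, neglect), the count of types, and the exposure
duration in years.  The continuous response is an analogue of a regional
gray-matter eigenvariate: a baseline depressed by exposure during a
configurable sensitive age window and by the number of maltreatment
types, plus Gaussian noise.

Exposure episodes are single contiguous runs: an onset age is drawn from
``onset_distribution`` and each subsequent year stays exposed with
probability ``episode_persistence`` (a geometric episode length,
truncated at the last bin).  The default persistence 0.98 with a uniform
onset over 16 annual bins gives a mean duration close to the 7.7 years
typical of such cohorts.  Type indicators are drawn independently at the
configured prevalences; a subject for whom every type indicator comes up
zero has no maltreatment exposure, so their annual record is cleared.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from ._rng import spawn_rng

__all__ = [
    "MALTREATMENT_TYPES",
    "TSCC_SUBSCALES",
    "SimConfig",
    "ExposureHistory",
    "CohortTable",
    "sample_exposure_history",
    "generate_response",
    "simulate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

MALTREATMENT_TYPES = ("physical", "emotional", "sexual", "neglect")
TSCC_SUBSCALES = ("tscc_anx", "tscc_dep", "tscc_ang", "tscc_pts", "tscc_dis", "tscc_sc")

# prevalences observed in a 21-child cohort: 7, 11, 2 and 16 children
_DEFAULT_PREVALENCE = {
    "physical": 7 / 21,
    "emotional": 11 / 21,
    "sexual": 2 / 21,
    "neglect": 16 / 21,
}


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    effect_size is the response drop per exposed year inside
    ``effect_window`` (positive = volume reduction); ``type_effect`` is
    the response shift per maltreatment type experienced (negative =
    reduction).  Both are in units of ``noise_sd`` when ``noise_sd=1``.
    """

    n_subjects: int = 21
    max_age_bin: int = 16
    prenatal_prevalence: float = 0.25
    type_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    episode_persistence: float = 0.98
    onset_distribution: Sequence[float] | None = None  # None = uniform over bins
    effect_window: tuple[int, ...] = (5, 6)  # ages 5-7 by default
    effect_size: float = 1.0
    type_effect: float = 0.0
    baseline: float = 0.0
    noise_sd: float = 1.0
    include_tscc: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = [self.prenatal_prevalence, self.episode_persistence]
        probs += [self.type_prevalence[t] for t in MALTREATMENT_TYPES]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.max_age_bin < 1:
            raise ConfigError("max_age_bin must be >= 1")
        if any(a < 0 or a >= self.max_age_bin for a in self.effect_window):
            raise ConfigError(
                f"effect_window {self.effect_window} outside bins 0..{self.max_age_bin - 1}"
            )
        if self.onset_distribution is not None:
            w = np.asarray(self.onset_distribution, dtype=float)
            if w.shape != (self.max_age_bin,) or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("onset_distribution must be a nonnegative vector over age bins")

    def onset_probs(self) -> np.ndarray:
        if self.onset_distribution is None:
            return np.full(self.max_age_bin, 1.0 / self.max_age_bin)
        w = np.asarray(self.onset_distribution, dtype=float)
        return w / w.sum()

    def to_dict(self) -> dict:
        rec = asdict(self)
        rec["type_prevalence"] = dict(self.type_prevalence)
        rec["effect_window"] = list(self.effect_window)
        if rec["onset_distribution"] is not None:
            rec["onset_distribution"] = list(rec["onset_distribution"])
        return rec

    @classmethod
    def from_dict(cls, rec: Mapping) -> "SimConfig":
        rec = dict(rec)
        if "effect_window" in rec:
            rec["effect_window"] = tuple(rec["effect_window"])
        cfg = cls(**rec)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            rec = yaml.safe_load(fh) or {}
        return cls.from_dict(rec)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ExposureHistory:
    """One subject's maltreatment exposure record with derived fields."""

    subject_id: int
    prenatal_dv: int
    annual: np.ndarray  # 0/1 per age bin
    types: dict[str, int]

    @property
    def n_types(self) -> int:
        return int(sum(self.types.values()))

    @property
    def duration_years(self) -> int:
        return int(self.annual.sum())


def age_bin_columns(max_age_bin: int) -> list[str]:
    return [f"age_{a}_{a + 1}" for a in range(max_age_bin)]


def sample_exposure_history(
    config: SimConfig, rng_state: int | np.random.Generator, subject_id: int = 0
) -> ExposureHistory:
    """Draw one subject: contiguous exposure episode plus type indicators."""
    config.validate()
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    prenatal = int(rng.random() < config.prenatal_prevalence)
    annual = np.zeros(config.max_age_bin, dtype=int)
    onset = int(rng.choice(config.max_age_bin, p=config.onset_probs()))
    annual[onset] = 1
    for a in range(onset + 1, config.max_age_bin):
        if rng.random() < config.episode_persistence:
            annual[a] = 1
        else:
            break
    types = {t: int(rng.random() < config.type_prevalence[t]) for t in MALTREATMENT_TYPES}
    if sum(types.values()) == 0:
        # no maltreatment type experienced => no exposed years
        annual[:] = 0
    return ExposureHistory(subject_id=subject_id, prenatal_dv=prenatal, annual=annual, types=types)


@dataclass
class CohortTable:
    """Subjects x predictors table with metadata and named responses."""

    frame: pd.DataFrame
    max_age_bin: int

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def age_columns(self) -> list[str]:
        return age_bin_columns(self.max_age_bin)

    @property
    def timing_columns(self) -> list[str]:
        return ["prenatal_dv"] + self.age_columns + ["duration_years"]

    @property
    def type_columns(self) -> list[str]:
        return list(MALTREATMENT_TYPES) + ["n_types"]

    @property
    def predictor_columns(self) -> list[str]:
        return self.timing_columns[:-1] + list(MALTREATMENT_TYPES) + ["n_types", "duration_years"]

    @property
    def response_names(self) -> list[str]:
        reserved = {"subject_id", *self.predictor_columns}
        return [c for c in self.frame.columns if c not in reserved]

    def category(self, column: str) -> str:
        if column == "prenatal_dv":
            return "prenatal"
        if column in self.age_columns:
            return "age-bin"
        if column == "duration_years":
            return "duration"
        if column in MALTREATMENT_TYPES:
            return "type"
        if column == "n_types":
            return "n_types"
        return "response"

    def design(self, columns: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
        """Predictor matrix + names + categories for the given columns."""
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort is missing columns: {missing}")
        X = self.frame[list(columns)].to_numpy(dtype=float)
        return X, list(columns), [self.category(c) for c in columns]

    def response(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise SchemaError(f"cohort has no response column {name!r}")
        return self.frame[name].to_numpy(dtype=float)


def generate_response(
    cohort: CohortTable, config: SimConfig, rng_state: int | np.random.Generator
) -> np.ndarray:
    """Raw (unscaled) regional-signal analogue for every subject.

    y_i = baseline - effect_size * (exposed years inside effect_window)
          + type_effect * n_types_i + N(0, noise_sd).
    """
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    window_cols = [age_bin_columns(config.max_age_bin)[a] for a in config.effect_window]
    missing = [c for c in window_cols if c not in cohort.frame.columns]
    if missing:
        raise SchemaError(f"effect_window columns absent from cohort: {missing}")
    window_years = (
        cohort.frame[window_cols].to_numpy(dtype=float).sum(axis=1)
        if window_cols
        else np.zeros(cohort.n_subjects)
    )
    n_types = cohort.frame["n_types"].to_numpy(dtype=float)
    noise = rng.normal(0.0, config.noise_sd, size=cohort.n_subjects)
    return config.baseline - config.effect_size * window_years + config.type_effect * n_types + noise


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Full synthetic cohort, deterministic given ``config.seed``.

    Column layout: subject_id, prenatal_dv, annual age bins, the four
    type indicators, n_types, duration_years, the gm_signal response and
    (optionally) six symptom subscales.
    """
    config.validate()
    if config.n_subjects < 2:
        raise ConfigError(f"n_subjects must be >= 2, got {config.n_subjects}")
    rng_hist = spawn_rng(config.seed, 0)
    histories = [
        sample_exposure_history(config, rng_hist, subject_id=i)
        for i in range(config.n_subjects)
    ]
    rec: dict[str, list] = {"subject_id": [h.subject_id for h in histories]}
    rec["prenatal_dv"] = [h.prenatal_dv for h in histories]
    for a, col in enumerate(age_bin_columns(config.max_age_bin)):
        rec[col] = [int(h.annual[a]) for h in histories]
    for t in MALTREATMENT_TYPES:
        rec[t] = [h.types[t] for h in histories]
    rec["n_types"] = [h.n_types for h in histories]
    rec["duration_years"] = [h.duration_years for h in histories]
    cohort = CohortTable(frame=pd.DataFrame(rec), max_age_bin=config.max_age_bin)
    cohort.frame["gm_signal"] = generate_response(cohort, config, spawn_rng(config.seed, 1))
    if config.include_tscc:
        # symptom scores rise (rather than fall) with window exposure; each
        # subscale gets independent noise from its own stream
        for s, name in enumerate(TSCC_SUBSCALES):
            raw = generate_response(cohort, config, spawn_rng(config.seed, 2 + s))
            cohort.frame[name] = 2.0 * config.baseline - raw
    return cohort


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """UTF-8 comma-separated cohort table, no index column."""
    cohort.frame.to_csv(path, index=False)


def cohort_to_csv_bytes(cohort: CohortTable) -> bytes:
    buf = io.StringIO()
    cohort.frame.to_csv(buf, index=False)
    return buf.getvalue().encode("utf-8")


def read_cohort_csv(path) -> CohortTable:
    """Read and validate a cohort CSV; missing values are rejected, never imputed."""
    frame = pd.read_csv(path)
    if frame.columns.duplicated().any():
        raise SchemaError("duplicate column names in cohort CSV")
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise SchemaError(f"missing values in columns: {bad}")
    age_cols = [c for c in frame.columns if c.startswith("age_")]
    if not age_cols:
        raise SchemaError("no annual age-bin columns (age_a_b) found")
    return CohortTable(frame=frame, max_age_bin=len(age_cols))
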