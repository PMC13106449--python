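"""Synthetic two-phase survey cohorts with known ground truth.

A cohort is a :class:`pandas.DataFrame` with one row per screened child and
the columns in :data:`COHORT_COLUMNS`.  Two generators are provided:

* :func:`simulate_population` — mixture generator: true status is Bernoulli
  per stratum and the screening score is drawn from a class-conditional
  distribution.  This produces both false-negative screens (true cases below
  the cutoff) and screen-positive non-cases, the two structures a
  misclassification-corrected analysis must handle.
* :func:`simulate_logistic_cohort` — model-consistent generator: latent
  status follows a logistic regression on the screening score with known
  coefficients.  Used for parameter-recovery and interval-coverage studies,
  where the data-generating process must match the analysis model.

Both generators share the downstream mechanics: a child screens positive
when the score meets the cutoff, screen-positives participate in the
diagnostic phase with probability ``logistic(intercept + slope * score)``,
and participants receive an error-prone diagnosis with sensitivity ``se``
and specificity ``sp`` with respect to their latent status.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._rng import rng_for

STRATA = ("LR", "ER", "HR")
SEXES = ("M", "F")
GRADES = (1, 2, 3)
SCQ_MAX = 39

COHORT_COLUMNS = (
    "id",
    "stratum",
    "grade",
    "sex",
    "scq_score",
    "screen_positive",
    "participated",
    "diagnosis",
    "true_status",
)


class CohortError(ValueError):
    """Invalid cohort configuration or malformed cohort data."""


@dataclass(frozen=True)
class StratumSpec:
    """A sampling stratum: its label, target population size and sampled size."""

    label: str
    population_size: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise CohortError(f"stratum {self.label!r}: population_size must be positive")
        if not (0 < self.sample_size <= self.population_size):
            raise CohortError(
                f"stratum {self.label!r}: sample_size must be in (0, population_size]"
            )


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise CohortError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class SimConfig:
    """Mixture-generator configuration.

    Defaults emulate the study population the analysis is designed for: three
    risk strata (mainstream schools LR, special-education schools ER, resource
    classes HR) with population sizes 34,392 / 292 / 112 and the realised
    sample of 8,565 LR children plus complete ER/HR enumeration; a screening
    cutoff of 11 on a 0–39 score; diagnostic sensitivity 0.85 and specificity
    0.75; and diagnostic-phase participation that increases with symptom
    severity (logistic in the screening score, about 25–30% on average).

    Score distributions given latent status are discretised truncated normals
    on [0, 39]: non-cases centred at 5 (SD 3), cases at 17 (SD 5), so that
    both screen-negative cases and screen-positive non-cases occur.
    """

    stratum_specs: tuple[StratumSpec, ...] = (
        StratumSpec("LR", 34_392, 8_565),
        StratumSpec("ER", 292, 292),
        StratumSpec("HR", 112, 112),
    )
    true_prevalence_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: {"LR": 0.015, "ER": 0.12, "HR": 0.95}
    )
    scq_params_case: tuple[float, float] = (17.0, 5.0)
    scq_params_noncase: tuple[float, float] = (5.0, 3.0)
    screen_cutoff: int = 11
    se: float = 0.85
    sp: float = 0.75
    participation_intercept: float = -3.2
    participation_slope_scq: float = 0.15
    male_fraction: float = 0.517
    grade_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stratum_specs:
            raise CohortError("at least one stratum is required")
        labels = [s.label for s in self.stratum_specs]
        if len(set(labels)) != len(labels):
            raise CohortError("duplicate stratum labels")
        for lab in labels:
            if lab not in self.true_prevalence_by_stratum:
                raise CohortError(f"no true prevalence given for stratum {lab!r}")
            _check_prob(f"prevalence[{lab}]", self.true_prevalence_by_stratum[lab])
        _check_prob("se", self.se)
        _check_prob("sp", self.sp)
        if self.se + self.sp <= 1.0:
            raise CohortError("se + sp must exceed 1 (informative diagnostic test)")
        if not (0 <= self.screen_cutoff <= SCQ_MAX):
            raise CohortError(f"screen_cutoff must lie in [0, {SCQ_MAX}]")
        _check_prob("male_fraction", self.male_fraction)
        if abs(sum(self.grade_probs) - 1.0) > 1e-9 or len(self.grade_probs) != len(GRADES):
            raise CohortError("grade_probs must be a length-3 simplex vector")
        for name, (_, sd) in (("scq_params_case", self.scq_params_case),
                              ("scq_params_noncase", self.scq_params_noncase)):
            if sd <= 0:
                raise CohortError(f"{name}: scale must be positive")


@dataclass(frozen=True)
class LogisticSimConfig:
    """Model-consistent generator: logit P(case | score) = beta0 + beta1 * score.

    Screening scores are drawn per stratum from a discretised truncated
    normal, so strata differ in score (hence risk) composition while the
    status-given-score relation is exactly logistic — the assumption of the
    latent analysis model.  Defaults use a steep slope so nearly all latent
    cases exceed the screening cutoff.
    """

    stratum_specs: tuple[StratumSpec, ...] = (
        StratumSpec("LR", 34_392, 600),
        StratumSpec("ER", 292, 150),
        StratumSpec("HR", 112, 50),
    )
    scq_params_by_stratum: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"LR": (6.0, 4.0), "ER": (10.0, 5.0), "HR": (18.0, 6.0)}
    )
    beta0: float = -8.0
    beta1: float = 0.45
    screen_cutoff: int = 11
    se: float = 0.85
    sp: float = 0.75
    participation_intercept: float = -3.2
    participation_slope_scq: float = 0.15
    male_fraction: float = 0.517
    grade_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stratum_specs:
            raise CohortError("at least one stratum is required")
        for s in self.stratum_specs:
            if s.label not in self.scq_params_by_stratum:
                raise CohortError(f"no score distribution for stratum {s.label!r}")
        _check_prob("se", self.se)
        _check_prob("sp", self.sp)
        if self.se + self.sp <= 1.0:
            raise CohortError("se + sp must exceed 1")
        if not (0 <= self.screen_cutoff <= SCQ_MAX):
            raise CohortError(f"screen_cutoff must lie in [0, {SCQ_MAX}]")


def _discretised_truncnorm(rng: np.random.Generator, loc: float, scale: float, n: int) -> np.ndarray:
    a, b = (0 - loc) / scale, (SCQ_MAX - loc) / scale
    raw = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    return np.clip(np.rint(raw), 0, SCQ_MAX).astype(int)


def _downstream(
    rng: np.random.Generator,
    scq: np.ndarray,
    true_status: np.ndarray,
    cutoff: int,
    se: float,
    sp: float,
    part_intercept: float,
    part_slope: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Screening, participation and error-prone diagnosis given latent status."""
    screen_pos = scq >= cutoff
    p_part = expit(part_intercept + part_slope * scq)
    participated = np.where(screen_pos, rng.random(scq.size) < p_part, False)
    p_diag_pos = np.where(true_status, se, 1.0 - sp)
    diag_draw = rng.random(scq.size) < p_diag_pos
    diagnosis = np.full(scq.size, pd.NA, dtype=object)
    mask = screen_pos & participated
    diagnosis[mask] = np.where(diag_draw[mask], "positive", "negative")
    return screen_pos, participated, diagnosis


def _demographics(rng: np.random.Generator, n: int, male_fraction: float,
                  grade_probs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    sex = np.where(rng.random(n) < male_fraction, "M", "F")
    grade = rng.choice(GRADES, size=n, p=np.asarray(grade_probs))
    return sex, grade


def _assemble(stratum_frames: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(stratum_frames, ignore_index=True)
    df["participated"] = df["participated"].astype("boolean")
    # participation is undefined for screen-negatives
    df.loc[~df["screen_positive"], "participated"] = pd.NA
    df["true_status"] = df["true_status"].astype("boolean")
    df["diagnosis"] = df["diagnosis"].astype("string")
    return df


def simulate_population(config: SimConfig) -> pd.DataFrame:
    """Simulate a screened cohort from the mixture generator.

    Reproducible: the same config (including seed) yields an identical frame.
    """
    frames = []
    for k, spec in enumerate(config.stratum_specs):
        rng = rng_for(config.seed, "cohort", k)
        n = spec.sample_size
        prev = config.true_prevalence_by_stratum[spec.label]
        true_status = rng.random(n) < prev
        scq = np.empty(n, dtype=int)
        n_case = int(true_status.sum())
        scq[true_status] = _discretised_truncnorm(rng, *config.scq_params_case, n_case)
        scq[~true_status] = _discretised_truncnorm(rng, *config.scq_params_noncase, n - n_case)
        screen_pos, part, diag = _downstream(
            rng, scq, true_status, config.screen_cutoff, config.se, config.sp,
            config.participation_intercept, config.participation_slope_scq,
        )
        sex, grade = _demographics(rng, n, config.male_fraction, config.grade_probs)
        frames.append(pd.DataFrame({
            "id": [f"{spec.label}-{i:06d}" for i in range(n)],
            "stratum": spec.label,
            "grade": grade,
            "sex": sex,
            "scq_score": scq,
            "screen_positive": screen_pos,
            "participated": part,
            "diagnosis": diag,
            "true_status": true_status,
        }))
    return _assemble(frames)


def simulate_logistic_cohort(config: LogisticSimConfig) -> pd.DataFrame:
    """Simulate a cohort whose latent status follows the analysis model exactly."""
    frames = []
    for k, spec in enumerate(config.stratum_specs):
        rng = rng_for(config.seed, "cohort", k)
        n = spec.sample_size
        scq = _discretised_truncnorm(rng, *config.scq_params_by_stratum[spec.label], n)
        p_case = expit(config.beta0 + config.beta1 * scq)
        true_status = rng.random(n) < p_case
        screen_pos, part, diag = _downstream(
            rng, scq, true_status, config.screen_cutoff, config.se, config.sp,
            config.participation_intercept, config.participation_slope_scq,
        )
        sex, grade = _demographics(rng, n, config.male_fraction, config.grade_probs)
        frames.append(pd.DataFrame({
            "id": [f"{spec.label}-{i:06d}" for i in range(n)],
            "stratum": spec.label,
            "grade": grade,
            "sex": sex,
            "scq_score": scq,
            "screen_positive": screen_pos,
            "participated": part,
            "diagnosis": diag,
            "true_status": true_status,
        }))
    return _assemble(frames)


def validate_cohort(df: pd.DataFrame, cutoff: int | None = None,
                    allowed_strata: tuple[str, ...] | None = None) -> None:
    """Check cohort invariants; raise :class:`CohortError` naming the first bad row.

    ``allowed_strata`` optionally restricts stratum labels (e.g. the standard
    LR/ER/HR design); labels are otherwise free-form.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"missing columns: {missing}")
    if allowed_strata is not None:
        bad = ~df["stratum"].isin(allowed_strata)
        if bad.any():
            raise CohortError(
                f"row {int(np.flatnonzero(bad)[0])}: unknown stratum label "
                f"(expected one of {list(allowed_strata)})"
            )
    scq = df["scq_score"]
    bad = (scq < 0) | (scq > SCQ_MAX)
    if bad.any():
        raise CohortError(f"row {int(np.flatnonzero(bad)[0])}: scq_score outside [0, {SCQ_MAX}]")
    bad = ~df["grade"].isin(GRADES)
    if bad.any():
        raise CohortError(f"row {int(np.flatnonzero(bad)[0])}: grade not in {GRADES}")
    bad = ~df["sex"].isin(SEXES)
    if bad.any():
        raise CohortError(f"row {int(np.flatnonzero(bad)[0])}: sex not in {SEXES}")
    if cutoff is not None:
        expected = scq >= cutoff
        bad = df["screen_positive"].to_numpy(dtype=bool) != expected.to_numpy()
        if bad.any():
            raise CohortError(
                f"row {int(np.flatnonzero(bad)[0])}: screen_positive inconsistent "
                f"with scq_score >= {cutoff}"
            )
    part = df["participated"]
    bad = (~df["screen_positive"]) & part.notna()
    if bad.any():
        raise CohortError(
            f"row {int(np.flatnonzero(bad.to_numpy())[0])}: participation defined "
            "for a screen-negative child"
        )
    bad = df["screen_positive"] & part.isna()
    if bad.any():
        raise CohortError(
            f"row {int(np.flatnonzero(bad.to_numpy())[0])}: participation missing "
            "for a screen-positive child"
        )
    diag = df["diagnosis"]
    ok_values = diag.isna() | diag.isin(["positive", "negative"])
    if not ok_values.all():
        raise CohortError(
            f"row {int(np.flatnonzero(~ok_values.to_numpy())[0])}: diagnosis must be "
            "'positive', 'negative' or missing"
        )
    should_be_missing = (~df["screen_positive"]) | (part.isna() | ~part.fillna(False))
    bad = should_be_missing.to_numpy() & diag.notna().to_numpy()
    if bad.any():
        raise CohortError(
            f"row {int(np.flatnonzero(bad)[0])}: diagnosis present without participation"
        )
    bad = (~should_be_missing.to_numpy()) & diag.isna().to_numpy()
    if bad.any():
        raise CohortError(
            f"row {int(np.flatnonzero(bad)[0])}: diagnosis missing for a participant"
        )


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (header = :data:`COHORT_COLUMNS`, missing = empty field)."""
    validate_cohort(df)
    out = df.loc[:, COHORT_COLUMNS].copy()
    for col in ("screen_positive",):
        out[col] = out[col].map({True: "True", False: "False"})
    out["participated"] = out["participated"].map({True: "True", False: "False"}).astype("string")
    out["true_status"] = out["true_status"].map({True: "True", False: "False"}).astype("string")
    out.to_csv(path, index=False)


def read_cohort(path, cutoff: int | None = None,
                allowed_strata: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortError(f"missing columns: {missing}")

    def _bool(col: str, required: bool) -> pd.Series:
        s = raw[col]
        bad = ~s.isin(["True", "False"] + ([] if required else [""]))
        if bad.any():
            raise CohortError(f"row {int(np.flatnonzero(bad)[0])}: bad boolean in {col!r}")
        return s.map({"True": True, "False": False, "": pd.NA}).astype("boolean")

    try:
        grade = pd.to_numeric(raw["grade"], errors="raise").astype(int)
        scq = pd.to_numeric(raw["scq_score"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise CohortError(f"non-numeric grade/scq_score: {exc}") from exc

    df = pd.DataFrame({
        "id": raw["id"],
        "stratum": raw["stratum"],
        "grade": grade,
        "sex": raw["sex"],
        "scq_score": scq,
        "screen_positive": _bool("screen_positive", required=True).astype(bool),
        "participated": _bool("participated", required=False),
        "diagnosis": raw["diagnosis"].replace("", pd.NA).astype("string"),
        "true_status": _bool("true_status", required=False),
    })
    validate_cohort(df, cutoff=cutoff, allowed_strata=allowed_strata)
    return df


def config_to_dict(config) -> dict:
    """SimConfig/LogisticSimConfig as a plain dict (YAML/JSON friendly)."""
    d = dataclasses.asdict(config)
    d["stratum_specs"] = [dataclasses.asdict(s) for s in config.stratum_specs]
    if "true_prevalence_by_stratum" in d:
        d["true_prevalence_by_stratum"] = dict(d["true_prevalence_by_stratum"])
    if "scq_params_by_stratum" in d:
        d["scq_params_by_stratum"] = {k: list(v) for k, v in d["scq_params_by_stratum"].items()}
    return d


def config_from_dict(d: Mapping, kind: str = "mixture"):
    """Inverse of :func:`config_to_dict`; ``kind`` is 'mixture' or 'logistic'."""
    d = dict(d)
    d["stratum_specs"] = tuple(StratumSpec(**s) for s in d["stratum_specs"])
    for key in ("scq_params_case", "scq_params_noncase", "grade_probs"):
        if key in d:
            d[key] = tuple(d[key])
    if "scq_params_by_stratum" in d:
        d["scq_params_by_stratum"] = {k: tuple(v) for k, v in d["scq_params_by_stratum"].items()}
    cls = SimConfig if kind == "mixture" else LogisticSimConfig
    return cls(**d)
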