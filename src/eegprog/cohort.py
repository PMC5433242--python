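"""Synthetic cohorts of comatose patients after cardiac arrest.

The generator emulates the statistical structure of a two-center cohort of
388 ICU patients monitored with continuous EEG: a roughly even split of
good (CPC 1-2) and poor (CPC 3-5) six-month outcomes, EEG background
categories at 12 and 24 hours with realistic missingness (late monitoring
start, artifacts, death before 24 hours), ICU and general-ward stay
durations, death and treatment-withdrawal days, and SSEP testing
indicators.  The default calibration encodes the published marginals:
poor outcome in 197/388, an unfavorable EEG at 24 h in 52/179 assessable
poor-outcome patients and 0/178 good-outcome patients, a favorable EEG at
12 h in 63/123 (good) versus 15/125 (poor), and the printed stay-duration
moments.

Stay durations follow lognormal laws moment-matched to the printed
mean/SD (nonnegative and right-skewed, which is all the printed moments
constrain).  For patients who die after day 1, the withdrawal day is drawn
first and death follows after an exponential residual interval, so that
counterfactual earlier withdrawal can preserve each patient's
withdrawal-to-death interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .eeg_classify import EEGCategory, PrognosticGroup, prognostic_group

__all__ = [
    "DurationLaw",
    "CohortParams",
    "PatientRecord",
    "default_calibration",
    "generate_cohort",
    "summarize_cohort",
    "validate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "params_to_yaml",
    "params_from_yaml",
    "COHORT_COLUMNS",
]

PathLike = Union[str, Path]

COHORT_COLUMNS = [
    "patient_id",
    "cpc6",
    "outcome",
    "eeg12",
    "eeg24",
    "eeg12_missing_reason",
    "eeg24_missing_reason",
    "eeg_start_hours",
    "icu_days",
    "gw_days",
    "died",
    "death_day",
    "withdrawal_day",
    "ssep_performed",
    "ssep_absent",
]


@dataclass(frozen=True)
class DurationLaw:
    """A nonnegative right-skewed law described by its mean and SD.

    Sampled as a lognormal moment-matched to (mean, sd); sd == 0 degenerates
    to the constant ``mean``.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be nonnegative")

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.mean == 0 or self.sd == 0:
            return np.full(size, self.mean) if size else self.mean
        sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size)


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Conditional probabilities are stated given the subgroup named in the
    field; ``default_calibration`` fills them from the published counts.
    """

    n_patients: int = 388
    p_poor: float = 197 / 388
    # EEG at 24 h, among patients assessable at that hour
    p_unfav24_given_poor: float = 52 / 179
    p_unfav24_given_good: float = 0.0
    # EEG at 12 h, among patients assessable at that hour
    p_fav12_given_good: float = 63 / 123
    p_fav12_given_poor: float = 15 / 125
    # missingness machinery
    start_hours_median: float = 6.8
    start_hours_sigma: float = 1.269  # log-SD; yields P(start > 12 h) ~= 127/388
    p_eeg12_artifact: float = 19 / 261  # given monitoring started before 12 h
    p_eeg24_artifact: float = 21 / 377  # given alive at 24 h
    # mortality structure within the poor-outcome group
    p_early_death_given_poor: float = 11 / 197  # death before 24 h
    p_death_given_unfav24: float = 51 / 52
    p_death_given_other_poor: float = 115 / 134
    # stay durations (days)
    icu_days_distribution: DurationLaw = DurationLaw(8.2, 10.8)
    gw_days_distribution: DurationLaw = DurationLaw(9.6, 12.7)
    withdrawal_day_distribution: DurationLaw = DurationLaw(4.6, 2.9)
    unfav_withdrawal_day_distribution: DurationLaw = DurationLaw(3.9, 1.8)
    withdrawal_to_death_mean: float = 0.2  # days; exponential residual interval
    p_gw_after_withdrawal: float = 0.09  # deaths outside the ICU
    gw_after_withdrawal_distribution: DurationLaw = DurationLaw(6.7, 12.0)
    # SSEP testing
    p_ssep_given_poor: float = 139 / 197
    p_ssep_given_good: float = 39 / 187
    p_ssep_absent_given_poor: float = 65 / 139  # among performed
    p_ssep_absent_given_good: float = 7 / 39
    # category composition inside each prognostic group (not published;
    # plausible splits documented in the methods note)
    p_inter24_given_good_residual: float = 0.15
    p_inter24_given_poor_residual: float = 0.35
    p_unfav12_given_good_residual: float = 0.70
    p_unfav12_given_poor_residual: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        for name, value in asdict(self).items():
            if name.startswith("p_") and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} is not a probability")
        if self.withdrawal_to_death_mean < 0:
            raise ValueError("withdrawal_to_death_mean must be nonnegative")


_UNFAV_SPLIT = [
    (EEGCategory.ISOELECTRIC, 0.25),
    (EEGCategory.LOW_VOLTAGE, 0.35),
    (EEGCategory.BURST_SUPPRESSION_IDENTICAL, 0.40),
]
_INTER_SPLIT = [
    (EEGCategory.EPILEPTIFORM, 0.5),
    (EEGCategory.BURST_SUPPRESSION_HETEROGENEOUS, 0.5),
]
_FAV_SPLIT = [
    (EEGCategory.CONTINUOUS_SLOW, 0.6),
    (EEGCategory.CONTINUOUS_NORMAL, 0.4),
]


def default_calibration() -> CohortParams:
    """Parameters encoding the published cohort marginals (n = 388)."""
    return CohortParams()


@dataclass
class PatientRecord:
    """One patient's outcome, EEG categories, stays and event days."""

    patient_id: str
    cpc6: int
    eeg12: Optional[EEGCategory] = None
    eeg24: Optional[EEGCategory] = None
    eeg12_missing_reason: str = ""
    eeg24_missing_reason: str = ""
    eeg_start_hours: float = 6.0
    icu_days: float = 0.0
    gw_days: float = 0.0
    died: bool = False
    death_day: Optional[float] = None
    withdrawal_day: Optional[float] = None
    ssep_performed: bool = False
    ssep_absent: bool = False

    @property
    def outcome(self) -> str:
        """Good for CPC 1-2, poor for CPC 3-5."""
        return "good" if self.cpc6 in (1, 2) else "poor"

    def validate(self) -> None:
        if self.cpc6 not in (1, 2, 3, 4, 5):
            raise ValueError("cpc6 must be 1..5")
        if self.died and (self.cpc6 != 5 or self.death_day is None):
            raise ValueError("died implies cpc6 == 5 and a death day")
        if not self.died and self.cpc6 == 5:
            raise ValueError("cpc6 == 5 implies died")
        if self.withdrawal_day is not None and self.death_day is not None:
            if self.withdrawal_day > self.death_day + 1e-9:
                raise ValueError("withdrawal day must not exceed death day")
        if self.ssep_absent and not self.ssep_performed:
            raise ValueError("ssep_absent implies ssep_performed")
        if self.icu_days < 0 or self.gw_days < 0:
            raise ValueError("stay durations must be nonnegative")

    def as_dict(self) -> dict:
        d = {c: getattr(self, c) for c in COHORT_COLUMNS if c != "outcome"}
        d["outcome"] = self.outcome
        d["eeg12"] = None if self.eeg12 is None else EEGCategory(self.eeg12).value
        d["eeg24"] = None if self.eeg24 is None else EEGCategory(self.eeg24).value
        return d


def _pick(rng: np.random.Generator, split) -> EEGCategory:
    cats, weights = zip(*split)
    w = np.asarray(weights, dtype=float)
    return cats[int(rng.choice(len(cats), p=w / w.sum()))]


def _draw_patient(i: int, p: CohortParams, rng: np.random.Generator) -> PatientRecord:
    poor = rng.random() < p.p_poor
    rec = PatientRecord(patient_id=f"P{i + 1:04d}", cpc6=0)

    # --- outcome, 24-h EEG and death machinery -------------------------
    if poor:
        early_death = rng.random() < p.p_early_death_given_poor
        if early_death:
            rec.cpc6, rec.died = 5, True
            rec.death_day = float(rng.uniform(0.15, 1.0))
            rec.eeg24_missing_reason = "death_before_24h"
            unfav24 = False
            assessable24 = False
        else:
            assessable24 = rng.random() >= p.p_eeg24_artifact
            if not assessable24:
                rec.eeg24_missing_reason = "artifact"
            unfav24 = assessable24 and rng.random() < p.p_unfav24_given_poor
            p_die = p.p_death_given_unfav24 if unfav24 else p.p_death_given_other_poor
            rec.died = rng.random() < p_die
            rec.cpc6 = 5 if rec.died else 3
        if assessable24:
            if unfav24:
                rec.eeg24 = _pick(rng, _UNFAV_SPLIT)
            elif rng.random() < p.p_inter24_given_poor_residual:
                rec.eeg24 = _pick(rng, _INTER_SPLIT)
            else:
                rec.eeg24 = _pick(rng, _FAV_SPLIT)
    else:
        rec.cpc6 = 1 if rng.random() < 0.7 else 2
        assessable24 = rng.random() >= p.p_eeg24_artifact
        if not assessable24:
            rec.eeg24_missing_reason = "artifact"
        else:
            if rng.random() < p.p_unfav24_given_good:
                rec.eeg24 = _pick(rng, _UNFAV_SPLIT)
            elif rng.random() < p.p_inter24_given_good_residual:
                rec.eeg24 = _pick(rng, _INTER_SPLIT)
            else:
                rec.eeg24 = _pick(rng, _FAV_SPLIT)

    # --- 12-h EEG with missingness ------------------------------------
    rec.eeg_start_hours = float(
        rng.lognormal(math.log(p.start_hours_median), p.start_hours_sigma)
    )
    if rec.death_day is not None and rec.death_day <= 0.5:
        rec.eeg12_missing_reason = "death_before_12h"
    elif rec.eeg_start_hours > 12.0:
        rec.eeg12_missing_reason = "late_start"
    elif rng.random() < p.p_eeg12_artifact:
        rec.eeg12_missing_reason = "artifact"
    else:
        p_fav = p.p_fav12_given_poor if poor else p.p_fav12_given_good
        if rng.random() < p_fav:
            rec.eeg12 = _pick(rng, _FAV_SPLIT)
        else:
            p_unfav = (
                p.p_unfav12_given_poor_residual if poor else p.p_unfav12_given_good_residual
            )
            rec.eeg12 = _pick(
                rng, _UNFAV_SPLIT if rng.random() < p_unfav else _INTER_SPLIT
            )

    # --- stays, withdrawal and death days ------------------------------
    unfav24_group = (
        rec.eeg24 is not None
        and prognostic_group(rec.eeg24) == PrognosticGroup.UNFAVORABLE
    )
    if not rec.died:
        rec.icu_days = float(p.icu_days_distribution.sample(rng))
        rec.gw_days = float(p.gw_days_distribution.sample(rng))
    elif rec.eeg24_missing_reason == "death_before_24h":
        rec.icu_days = float(rec.death_day)
        rec.gw_days = 0.0
    else:
        law = (
            p.unfav_withdrawal_day_distribution
            if unfav24_group
            else p.withdrawal_day_distribution
        )
        wd = max(float(law.sample(rng)), 1.05)
        residual = float(rng.exponential(p.withdrawal_to_death_mean))
        rec.withdrawal_day = wd
        rec.icu_days = wd + residual
        if rng.random() < p.p_gw_after_withdrawal:
            rec.gw_days = float(p.gw_after_withdrawal_distribution.sample(rng))
        else:
            rec.gw_days = 0.0
        rec.death_day = rec.icu_days + rec.gw_days

    # --- SSEP -----------------------------------------------------------
    p_ssep = p.p_ssep_given_poor if poor else p.p_ssep_given_good
    rec.ssep_performed = rng.random() < p_ssep
    if rec.ssep_performed:
        p_abs = p.p_ssep_absent_given_poor if poor else p.p_ssep_absent_given_good
        rec.ssep_absent = rng.random() < p_abs

    rec.validate()
    return rec


def generate_cohort(params: CohortParams, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a cohort table, one row per patient.

    Deterministic for a given (params, seed); ``seed`` defaults to
    ``params.seed``.  Returns a DataFrame with :data:`COHORT_COLUMNS`.
    """
    if not isinstance(params, CohortParams):
        raise TypeError("params must be a CohortParams")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    records = [_draw_patient(i, params, rng) for i in range(params.n_patients)]
    df = pd.DataFrame([r.as_dict() for r in records], columns=COHORT_COLUMNS)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise if any row violates the patient-record invariants."""
    if df.empty:
        raise ValueError("cohort is empty")
    good = df["cpc6"].isin([1, 2])
    if not (df.loc[good, "outcome"] == "good").all() or not (
        df.loc[~good, "outcome"] == "poor"
    ).all():
        raise ValueError("outcome label inconsistent with CPC")
    died = df["died"].astype(bool)
    if not (df.loc[died, "cpc6"] == 5).all() or df.loc[died, "death_day"].isna().any():
        raise ValueError("died implies CPC 5 with a death day")
    both = died & df["withdrawal_day"].notna()
    if (df.loc[both, "withdrawal_day"] > df.loc[both, "death_day"] + 1e-9).any():
        raise ValueError("withdrawal after death")
    if (df["ssep_absent"].astype(bool) & ~df["ssep_performed"].astype(bool)).any():
        raise ValueError("ssep_absent without ssep_performed")
    if (df["icu_days"] < 0).any() or (df["gw_days"] < 0).any():
        raise ValueError("negative stay durations")


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome-group counts and means, plus EEG missingness tallies.

    Returns a table indexed by statistic with one column per outcome group,
    in the spirit of a baseline-characteristics table.
    """
    if cohort.empty:
        raise ValueError("cannot summarize an empty cohort")
    rows: dict[str, dict[str, object]] = {}
    for outcome, g in cohort.groupby("outcome"):
        col: dict[str, object] = {"n": len(g)}
        for name in ("eeg_start_hours", "icu_days", "gw_days", "death_day", "withdrawal_day"):
            col[f"mean_{name}"] = g[name].mean()
        col["n_died"] = int(g["died"].sum())
        col["n_ssep_performed"] = int(g["ssep_performed"].sum())
        col["n_ssep_absent"] = int(g["ssep_absent"].sum())
        for hour in (12, 24):
            cats = g[f"eeg{hour}"].dropna().map(prognostic_group)
            col[f"n_assessable_{hour}h"] = int(cats.size)
            for grp in (PrognosticGroup.UNFAVORABLE, PrognosticGroup.INTERMEDIATE, PrognosticGroup.FAVORABLE):
                col[f"n_{grp.value}_{hour}h"] = int((cats == grp).sum())
            reasons = g.loc[g[f"eeg{hour}"].isna(), f"eeg{hour}_missing_reason"]
            for reason, count in reasons.value_counts().items():
                col[f"n_missing_{hour}h_{reason}"] = int(count)
        rows[outcome] = col
    return pd.DataFrame(rows).rename_axis("statistic")


# ---------------------------------------------------------------------------
# serialization

def write_cohort_csv(cohort: pd.DataFrame, path: PathLike) -> None:
    """Write the cohort with the fixed documented header; missing as empty."""
    cohort.to_csv(path, index=False, na_rep="", columns=COHORT_COLUMNS)


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "eeg12": "string", "eeg24": "string"},
        keep_default_na=True,
    )
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    for col in ("died", "ssep_performed", "ssep_absent"):
        df[col] = df[col].astype(bool)
    for col in ("eeg12", "eeg24"):
        df[col] = df[col].astype(object).where(df[col].notna(), None)
    for col in ("eeg12_missing_reason", "eeg24_missing_reason"):
        df[col] = df[col].fillna("")
    return df[COHORT_COLUMNS]


def params_to_yaml(params: CohortParams, path: PathLike) -> None:
    d = asdict(params)
    for key, value in list(d.items()):
        if isinstance(value, dict) and set(value) == {"mean", "sd"}:
            d[key] = {"mean": float(value["mean"]), "sd": float(value["sd"])}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def params_from_yaml(path: PathLike) -> CohortParams:
    d = yaml.safe_load(Path(path).read_text())
    for key, value in list(d.items()):
        if isinstance(value, dict) and set(value) == {"mean", "sd"}:
            d[key] = DurationLaw(**value)
    return CohortParams(**d)
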