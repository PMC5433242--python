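"""Decision-analytic cost-minimization of EEG-based treatment withdrawal.

Three care pathways are compared from a hospital perspective:

* pathway 1 — current care;
* pathway 2 — counterfactual withdrawal of life-sustaining treatment at
  24 hours after arrest in patients with an unfavorable EEG at 24 hours;
* pathway 3 — the same decision taken at 72 hours.

The counterfactual preserves each patient's observed interval between
treatment withdrawal and death: withdrawal is moved earlier (never later),
death and the ICU stay shift with it, and long-run (180-day) mortality is
unchanged because the unfavorable pattern is assumed perfectly specific
for poor outcome.  Patients with favorable, intermediate or unassessable
EEG at 24 hours follow current care, as do patients who died before the
EEG at 24 hours existed.

Costs use fixed unit prices (ICU day EUR 2015, general-ward day EUR 443,
SSEP EUR 149, EEG EUR 21) and are accumulated in integer cents.  In the
withdrawal pathways an EEG is charged for every patient alive at 24 hours,
and the SSEP cost is dropped for patients whose unfavorable EEG alone
drives the decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .eeg_classify import PrognosticGroup, prognostic_group

__all__ = [
    "CostParams",
    "Pathway",
    "Scenario",
    "DecisionTree",
    "ScenarioResult",
    "PathwayComparison",
    "apply_scenario",
    "build_decision_tree",
    "pathway_costs",
    "survival_curve",
    "compare_pathways",
    "stay_reduction",
    "cost_difference",
]


@dataclass(frozen=True)
class CostParams:
    """Unit prices in EUR (2015 Dutch reference prices)."""

    icu_day_eur: float = 2015.0
    gw_day_eur: float = 443.0
    ssep_eur: float = 149.0
    eeg_eur: float = 21.0

    def __post_init__(self) -> None:
        if min(self.icu_day_eur, self.gw_day_eur, self.ssep_eur, self.eeg_eur) < 0:
            raise ValueError("unit prices must be nonnegative")


class Pathway(str, Enum):
    CURRENT_CARE = "current_care"
    WITHDRAW_24H = "withdraw_24h"
    WITHDRAW_72H = "withdraw_72h"


@dataclass(frozen=True)
class Scenario:
    """A care pathway; the decision day exists only for withdrawal pathways.

    Day 1 is the first 24 hours after arrest, so a decision "at 24 hours"
    closes ICU occupancy after day 1 and "at 72 hours" after day 3.
    """

    pathway: Pathway
    withdrawal_decision_day: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pathway == Pathway.CURRENT_CARE:
            if self.withdrawal_decision_day is not None:
                raise ValueError("current care has no decision day")
        else:
            expected = {Pathway.WITHDRAW_24H: 1.0, Pathway.WITHDRAW_72H: 3.0}[self.pathway]
            if self.withdrawal_decision_day is None:
                object.__setattr__(self, "withdrawal_decision_day", expected)
            elif self.withdrawal_decision_day <= 0:
                raise ValueError("decision day must be positive")


CURRENT_CARE = Scenario(Pathway.CURRENT_CARE)
WITHDRAW_24H = Scenario(Pathway.WITHDRAW_24H)
WITHDRAW_72H = Scenario(Pathway.WITHDRAW_72H)


def _unfavorable24(cohort: pd.DataFrame) -> pd.Series:
    cats = cohort["eeg24"]
    out = pd.Series(False, index=cohort.index)
    mask = cats.notna()
    out.loc[mask] = (
        cats.loc[mask].map(prognostic_group) == PrognosticGroup.UNFAVORABLE
    )
    return out


def apply_scenario(cohort: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Counterfactual cohort under EEG-based earlier withdrawal.

    For every patient who died with an unfavorable EEG at 24 hours, the
    withdrawal day becomes ``min(observed, decision day)`` and the observed
    withdrawal-to-death interval is preserved, shifting the death day and
    shortening the ICU stay by the same amount (never lengthening it).
    All other patients — favorable/intermediate/unassessable EEG, survivors
    (including the unfavorable-EEG survivor), deaths before 24 hours — keep
    their observed trajectory.
    """
    if scenario.pathway == Pathway.CURRENT_CARE:
        raise ValueError("apply_scenario needs a withdrawal scenario")
    day = float(scenario.withdrawal_decision_day)
    out = cohort.copy(deep=True)
    target = (
        _unfavorable24(cohort)
        & cohort["died"].astype(bool)
        & cohort["death_day"].notna()
        & (cohort["death_day"] >= 1.0)
    )
    for idx in out.index[target]:
        wd = out.at[idx, "withdrawal_day"]
        death = float(out.at[idx, "death_day"])
        if pd.isna(wd):
            wd = death  # no recorded withdrawal: treat death itself as the endpoint
        wd = float(wd)
        new_wd = min(wd, day)
        delta = wd - new_wd
        if delta <= 0:
            continue
        out.at[idx, "withdrawal_day"] = new_wd
        out.at[idx, "death_day"] = death - delta
        out.at[idx, "icu_days"] = max(float(out.at[idx, "icu_days"]) - delta, 0.0)
    return out


@dataclass
class DecisionTree:
    """Day-branch occupancy model of a ward.

    ``counts[d-1]`` is the number of patients still present on day ``d``
    (1-based whole days, durations rounded up); ``probs[d-1]`` is that count
    divided by the count on day ``d-1`` (day 0 count = cohort size), the
    branch probability of staying another day.
    """

    n_patients: int
    counts: np.ndarray
    probs: np.ndarray

    @property
    def expected_days(self) -> float:
        """Expected whole days of occupancy: sum of cumulative branch products."""
        return float(np.cumprod(self.probs).sum()) if self.probs.size else 0.0


def build_decision_tree(cohort: pd.DataFrame, column: str = "icu_days") -> DecisionTree:
    """Branch probabilities per day from stay durations (ceiled to whole days)."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    days = np.ceil(cohort[column].to_numpy(dtype=float))
    n = len(days)
    max_day = int(days.max()) if n else 0
    counts = np.array([(days >= d).sum() for d in range(1, max_day + 1)], dtype=int)
    prev = np.concatenate(([n], counts[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(prev > 0, counts / prev, 0.0)
    return DecisionTree(n_patients=n, counts=counts, probs=probs)


@dataclass
class ScenarioResult:
    """Costs, stays and survival of one pathway."""

    scenario: Scenario
    n_patients: int
    unfav_n_alive_6m: int
    unfav_n_dead_6m: int
    unfav_mean_icu_days: float
    unfav_mean_gw_days: float
    cost_per_patient_eur: float
    total_cost_eur: float
    survival: np.ndarray  # alive fraction at days 0..horizon

    @property
    def unfav_mean_stay_days(self) -> float:
        return self.unfav_mean_icu_days + self.unfav_mean_gw_days


def _per_patient_cost_cents(
    cohort: pd.DataFrame, prices: CostParams, scenario: Scenario
) -> np.ndarray:
    if (cohort["icu_days"] < 0).any() or (cohort["gw_days"] < 0).any():
        raise ValueError("negative stay durations")
    icu_c = np.round(cohort["icu_days"].to_numpy(float) * prices.icu_day_eur * 100).astype(np.int64)
    gw_c = np.round(cohort["gw_days"].to_numpy(float) * prices.gw_day_eur * 100).astype(np.int64)
    ssep = cohort["ssep_performed"].to_numpy(bool).copy()
    eeg_c = np.zeros(len(cohort), dtype=np.int64)
    if scenario.pathway != Pathway.CURRENT_CARE:
        unfav = _unfavorable24(cohort).to_numpy()
        ssep &= ~unfav  # the EEG alone decides; no SSEP is billed
        death_day = cohort["death_day"].to_numpy(dtype=float, na_value=np.inf)
        alive_24h = (~cohort["died"].to_numpy(bool)) | (death_day >= 1.0)
        eeg_c[alive_24h] = int(round(prices.eeg_eur * 100))
    ssep_c = np.where(ssep, int(round(prices.ssep_eur * 100)), 0)
    return icu_c + gw_c + ssep_c + eeg_c


def survival_curve(cohort: pd.DataFrame, horizon_days: int = 180) -> np.ndarray:
    """Fraction of the cohort alive at each integer day 0..horizon.

    A patient counts as dead at day ``d`` when their death day is <= d; the
    value at the horizon equals 1 - deaths/n.
    """
    n = len(cohort)
    death_days = cohort.loc[cohort["died"].astype(bool), "death_day"].to_numpy(float)
    days = np.arange(horizon_days + 1)
    dead = (death_days[:, None] <= days[None, :]).sum(axis=0) if death_days.size else np.zeros_like(days)
    return 1.0 - dead / n


def pathway_costs(
    cohort: pd.DataFrame,
    prices: CostParams = CostParams(),
    scenario: Scenario = CURRENT_CARE,
    horizon_days: int = 180,
) -> ScenarioResult:
    """Per-patient and total costs plus stay/survival summaries for a pathway.

    ``cohort`` must already be the (possibly counterfactual) cohort for this
    scenario; use :func:`apply_scenario` first, or :func:`compare_pathways`
    for the full comparison.  Totals are exact sums of per-patient costs in
    cents.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    cents = _per_patient_cost_cents(cohort, prices, scenario)
    unfav = _unfavorable24(cohort)
    sub = cohort.loc[unfav]
    died = sub["died"].astype(bool)
    return ScenarioResult(
        scenario=scenario,
        n_patients=len(cohort),
        unfav_n_alive_6m=int((~died).sum()),
        unfav_n_dead_6m=int(died.sum()),
        unfav_mean_icu_days=float(sub["icu_days"].mean()) if len(sub) else float("nan"),
        unfav_mean_gw_days=float(sub["gw_days"].mean()) if len(sub) else float("nan"),
        cost_per_patient_eur=float(cents.sum()) / 100.0 / len(cohort),
        total_cost_eur=float(cents.sum()) / 100.0,
        survival=survival_curve(cohort, horizon_days),
    )


def stay_reduction(reference: ScenarioResult, alternative: ScenarioResult) -> float:
    """Reduction in mean ICU+GW days in the unfavorable-EEG subgroup."""
    return reference.unfav_mean_stay_days - alternative.unfav_mean_stay_days


def cost_difference(reference: ScenarioResult, alternative: ScenarioResult) -> float:
    """Per-patient cost reduction of the alternative pathway, EUR."""
    return reference.cost_per_patient_eur - alternative.cost_per_patient_eur


@dataclass
class PathwayComparison:
    """Results of all three pathways plus pairwise reductions."""

    results: dict[str, ScenarioResult]

    @property
    def cost_reduction_24h(self) -> float:
        return cost_difference(self.results["current_care"], self.results["withdraw_24h"])

    @property
    def cost_reduction_72h(self) -> float:
        return cost_difference(self.results["current_care"], self.results["withdraw_72h"])

    @property
    def stay_reduction_24h(self) -> float:
        return stay_reduction(self.results["current_care"], self.results["withdraw_24h"])

    @property
    def stay_reduction_72h(self) -> float:
        return stay_reduction(self.results["current_care"], self.results["withdraw_72h"])

    def as_frame(self) -> pd.DataFrame:
        rows = {}
        for name, r in self.results.items():
            rows[name] = {
                "unfav_alive_6m": r.unfav_n_alive_6m,
                "unfav_dead_6m": r.unfav_n_dead_6m,
                "unfav_mean_icu_days": r.unfav_mean_icu_days,
                "unfav_mean_gw_days": r.unfav_mean_gw_days,
                "cost_per_patient_eur": r.cost_per_patient_eur,
                "total_cost_eur": r.total_cost_eur,
            }
        return pd.DataFrame(rows).rename_axis("quantity")


def compare_pathways(
    cohort: pd.DataFrame,
    prices: CostParams = CostParams(),
    horizon_days: int = 180,
) -> PathwayComparison:
    """Run all three pathways on one observed cohort."""
    results = {
        "current_care": pathway_costs(cohort, prices, CURRENT_CARE, horizon_days),
        "withdraw_24h": pathway_costs(
            apply_scenario(cohort, WITHDRAW_24H), prices, WITHDRAW_24H, horizon_days
        ),
        "withdraw_72h": pathway_costs(
            apply_scenario(cohort, WITHDRAW_72H), prices, WITHDRAW_72H, horizon_days
        ),
    }
    return PathwayComparison(results)
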