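"""Diagnostic accuracy of EEG patterns for outcome prediction.

Sensitivity, specificity, PPV and NPV with exact (Clopper-Pearson) 95%
confidence intervals, plus Cohen's kappa for interrater agreement.  The
exact interval is used because at the boundary (e.g. 178/178 correct
negatives) it has the closed form lower bound (alpha/2)^(1/n), and both
exact and Wilson intervals round to the same whole percents for the
proportions this package reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa
from statsmodels.stats.proportion import proportion_confint

from .eeg_classify import PrognosticGroup, prognostic_group

__all__ = [
    "ConfusionCounts",
    "Estimate",
    "TestMetrics",
    "KappaResult",
    "confusion_counts",
    "binary_test_metrics",
    "clopper_pearson",
    "cohens_kappa",
    "predictive_table",
    "round_half_up_percent",
]


def round_half_up_percent(proportion: float) -> int:
    """Whole-percent display rounding, half away from zero."""
    return int(math.floor(proportion * 100.0 + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts: test = prognostic group present, condition = outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Estimate:
    """A proportion with its exact two-sided confidence interval."""

    numerator: int
    denominator: int
    point: float
    lower: float
    upper: float

    @property
    def percent(self) -> int:
        return round_half_up_percent(self.point)

    @property
    def ci_percent(self) -> tuple[int, int]:
        return (round_half_up_percent(self.lower), round_half_up_percent(self.upper))


@dataclass(frozen=True)
class TestMetrics:
    """Sensitivity/specificity/PPV/NPV; a metric with a zero denominator is None."""

    counts: ConfusionCounts
    sensitivity: Optional[Estimate]
    specificity: Optional[Estimate]
    ppv: Optional[Estimate]
    npv: Optional[Estimate]
    level: float = 0.95


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact central binomial confidence interval.

    At ``successes == n`` the lower bound is ``(alpha/2)**(1/n)``; at 0 the
    upper bound is ``1 - (alpha/2)**(1/n)``.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n with n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    return (0.0 if np.isnan(lo) else float(lo), 1.0 if np.isnan(hi) else float(hi))


def _estimate(numer: int, denom: int, level: float) -> Optional[Estimate]:
    if denom == 0:
        return None
    lo, hi = clopper_pearson(numer, denom, level)
    return Estimate(numer, denom, numer / denom, lo, hi)


def binary_test_metrics(counts: ConfusionCounts, level: float = 0.95) -> TestMetrics:
    """Accuracy measures with exact intervals from a 2x2 table.

    Undefined metrics (zero denominator) are flagged as ``None`` rather
    than reported as 0.
    """
    return TestMetrics(
        counts=counts,
        sensitivity=_estimate(counts.tp, counts.tp + counts.fn, level),
        specificity=_estimate(counts.tn, counts.tn + counts.fp, level),
        ppv=_estimate(counts.tp, counts.tp + counts.fp, level),
        npv=_estimate(counts.tn, counts.tn + counts.fn, level),
        level=level,
    )


def confusion_counts(
    cohort: pd.DataFrame,
    hour: int,
    group: PrognosticGroup | str,
    condition: str,
) -> ConfusionCounts:
    """Tally the 2x2 table for one prognostic group predicting one outcome.

    Patients whose EEG at ``hour`` is missing or unassessable are excluded,
    mirroring the footnoted denominators of the published baseline table.
    """
    if hour not in (12, 24):
        raise ValueError("hour must be 12 or 24")
    if condition not in ("good", "poor"):
        raise ValueError("condition must be 'good' or 'poor'")
    group = PrognosticGroup(group)
    col = cohort[f"eeg{hour}"]
    assessable = col.notna() & (col != PrognosticGroup.UNASSESSABLE.value)
    sub = cohort.loc[assessable]
    if sub.empty:
        raise ValueError(f"no assessable EEG at {hour} h")
    test_pos = sub[f"eeg{hour}"].map(prognostic_group) == group
    cond_pos = sub["outcome"] == condition
    return ConfusionCounts(
        tp=int((test_pos & cond_pos).sum()),
        fp=int((test_pos & ~cond_pos).sum()),
        fn=int((~test_pos & cond_pos).sum()),
        tn=int((~test_pos & ~cond_pos).sum()),
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    lower: float
    upper: float


def cohens_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    level: float = 0.95,
) -> KappaResult:
    """Cohen's kappa with its asymptotic confidence interval.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with chance agreement ``p_e`` from
    the marginal products.  Undefined (both raters constant and equal,
    ``p_e == 1``) raises ValueError.
    """
    a = pd.Series(list(ratings_a))
    b = pd.Series(list(ratings_b))
    if len(a) != len(b):
        raise ValueError("rating sequences must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two rated items")
    cats = sorted(set(a) | set(b), key=str)
    if len(cats) < 2:
        raise ValueError("kappa undefined: only one category present")
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats), dropna=False
    ).reindex(index=cats, columns=cats, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sm_kappa(table.to_numpy(), return_results=True)
    if not np.isfinite(res.kappa):
        raise ValueError("kappa undefined for these ratings")
    from scipy.stats import norm

    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    se = float(np.sqrt(res.var_kappa))
    return KappaResult(
        kappa=float(res.kappa),
        se=se,
        lower=max(-1.0, float(res.kappa) - z * se),
        upper=min(1.0, float(res.kappa) + z * se),
    )


def predictive_table(cohort: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Two-row accuracy report: favorable@12 h -> good, unfavorable@24 h -> poor.

    Columns give each metric as a whole percent with its interval, plus the
    underlying counts, in the layout of a predictive-values table.
    """
    specs = [
        ("favorable", 12, "good"),
        ("unfavorable", 24, "poor"),
    ]
    rows = []
    for group, hour, condition in specs:
        row: dict[str, object] = {
            "pattern": group,
            "hour": hour,
            "predicted_outcome": condition,
        }
        try:
            counts = confusion_counts(cohort, hour, PrognosticGroup(group), condition)
        except ValueError:
            # no assessable epoch at this hour: an empty, flagged row
            row.update({k: 0 for k in ("tp", "fp", "fn", "tn")})
            for name in ("specificity", "sensitivity", "ppv", "npv"):
                row[f"{name}_pct"] = None
                row[f"{name}_ci"] = None
            rows.append(row)
            continue
        metrics = binary_test_metrics(counts, level)
        row.update({"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn})
        for name in ("specificity", "sensitivity", "ppv", "npv"):
            est: Optional[Estimate] = getattr(metrics, name)
            if est is None:
                row[f"{name}_pct"] = None
                row[f"{name}_ci"] = None
            else:
                row[f"{name}_pct"] = est.percent
                lo, hi = est.ci_percent
                row[f"{name}_ci"] = f"{lo}-{hi}"
        rows.append(row)
    return pd.DataFrame(rows)
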