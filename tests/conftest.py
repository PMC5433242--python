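import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from eegprog.cohort import COHORT_COLUMNS, default_calibration, generate_cohort


def make_patient(
    patient_id="P0001",
    cpc6=1,
    eeg12=None,
    eeg24=None,
    icu_days=2.0,
    gw_days=1.0,
    died=False,
    death_day=None,
    withdrawal_day=None,
    ssep_performed=False,
    ssep_absent=False,
    eeg_start_hours=6.0,
):
    """One cohort row as a plain dict, for hand-built cohorts in tests."""
    return {
        "patient_id": patient_id,
        "cpc6": cpc6,
        "outcome": "good" if cpc6 in (1, 2) else "poor",
        "eeg12": eeg12,
        "eeg24": eeg24,
        "eeg12_missing_reason": "" if eeg12 else "late_start",
        "eeg24_missing_reason": "" if eeg24 else "artifact",
        "eeg_start_hours": eeg_start_hours,
        "icu_days": icu_days,
        "gw_days": gw_days,
        "died": died,
        "death_day": death_day,
        "withdrawal_day": withdrawal_day,
        "ssep_performed": ssep_performed,
        "ssep_absent": ssep_absent,
    }


def make_cohort(rows):
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default calibration, shared across tests."""
    return generate_cohort(default_calibration(), seed=12345)


def published_counts_exact_cohort():
    """A cohort whose 2x2 tallies equal the published baseline-table counts.

    Unfavorable EEG at 24 h: 52/179 poor, 0/178 good; favorable at 12 h:
    63/123 good, 15/125 poor.  The 12-h and 24-h tables are filled on
    disjoint patients (the joint distribution is not published), with the
    remaining patients' epochs left missing.
    """
    rows = []
    i = 0

    def add(n, **kw):
        nonlocal i
        for _ in range(n):
            i += 1
            rows.append(make_patient(patient_id=f"T{i:04d}", **kw))

    # 24-h table: poor outcome (condition positive)
    add(52, cpc6=5, eeg24="burst_suppression_identical", died=True, death_day=4.0, withdrawal_day=3.8)
    add(127, cpc6=4, eeg24="continuous_slow")
    # 24-h table: good outcome
    add(178, cpc6=1, eeg24="continuous_normal")
    # 12-h table on separate patients
    add(63, cpc6=1, eeg12="continuous_slow")
    add(60, cpc6=2, eeg12="low_voltage")
    add(15, cpc6=3, eeg12="continuous_normal")
    add(110, cpc6=5, eeg12="isoelectric", died=True, death_day=5.0, withdrawal_day=4.5)
    return make_cohort(rows)


@pytest.fixture(scope="session")
def published_counts_cohort():
    return published_counts_exact_cohort()
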