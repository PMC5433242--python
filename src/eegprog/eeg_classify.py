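"""Rule-based classification of EEG background patterns after cardiac arrest.

The visual classification used at the bedside distinguishes isoelectric,
low-voltage (<20 uV), burst-suppression (with or without identical bursts),
epileptiform, diffusely slowed and normal backgrounds.  This module
implements those rules as a deterministic decision cascade over sampled
epochs: a sliding peak-to-peak amplitude envelope operationalizes the
amplitude thresholds, suppressions and bursts are segmented from the
envelope, stereotypy of bursts is scored by waveform correlation, and
continuous patterns are split at a dominant frequency of 8 Hz.

Epileptiform activity (evolving seizures, generalized periodic discharges)
is a label-only category: it is never emitted by the cascade, which has no
spike/seizure detector by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import welch

__all__ = [
    "EEGCategory",
    "PrognosticGroup",
    "EEGThresholds",
    "Burst",
    "amplitude_envelope",
    "detect_suppressions",
    "detect_bursts",
    "identical_burst_score",
    "dominant_frequency",
    "classify_epoch",
    "prognostic_group",
    "is_artifact",
    "select_epoch",
    "PROGNOSTIC_MAP",
]


class EEGCategory(str, Enum):
    """EEG background categories at a fixed time point after arrest."""

    ISOELECTRIC = "isoelectric"
    LOW_VOLTAGE = "low_voltage"
    EPILEPTIFORM = "epileptiform"
    BURST_SUPPRESSION_IDENTICAL = "burst_suppression_identical"
    BURST_SUPPRESSION_HETEROGENEOUS = "burst_suppression_heterogeneous"
    CONTINUOUS_SLOW = "continuous_slow"
    CONTINUOUS_NORMAL = "continuous_normal"
    UNASSESSABLE = "unassessable"


class PrognosticGroup(str, Enum):
    """Collapse of the category taxonomy used for outcome prediction."""

    UNFAVORABLE = "unfavorable"
    INTERMEDIATE = "intermediate"
    FAVORABLE = "favorable"
    UNASSESSABLE = "unassessable"


PROGNOSTIC_MAP: dict[EEGCategory, PrognosticGroup] = {
    EEGCategory.ISOELECTRIC: PrognosticGroup.UNFAVORABLE,
    EEGCategory.LOW_VOLTAGE: PrognosticGroup.UNFAVORABLE,
    EEGCategory.BURST_SUPPRESSION_IDENTICAL: PrognosticGroup.UNFAVORABLE,
    EEGCategory.EPILEPTIFORM: PrognosticGroup.INTERMEDIATE,
    EEGCategory.BURST_SUPPRESSION_HETEROGENEOUS: PrognosticGroup.INTERMEDIATE,
    EEGCategory.CONTINUOUS_SLOW: PrognosticGroup.FAVORABLE,
    EEGCategory.CONTINUOUS_NORMAL: PrognosticGroup.FAVORABLE,
    EEGCategory.UNASSESSABLE: PrognosticGroup.UNASSESSABLE,
}


def prognostic_group(category: EEGCategory | str) -> PrognosticGroup:
    """Map an EEG category to its prognostic group.

    Isoelectric, low-voltage and burst-suppression with identical bursts are
    unfavorable; epileptiform and burst-suppression without identical bursts
    are intermediate; continuous patterns (slowed or normal) are favorable.
    """
    return PROGNOSTIC_MAP[EEGCategory(category)]


@dataclass(frozen=True)
class EEGThresholds:
    """Numeric thresholds of the classification rules.

    Amplitude bounds are peak-to-peak within a sliding ``envelope_window``:
    the clinical definitions ("<20 uV", "activity <10 uV") do not say
    peak-to-peak versus half-amplitude, and peak-to-peak over a short window
    is the convention used when reading paper tracings.

    Parameters without a stated clinical value (``isoelectric_max``,
    ``identical_corr_min``, ``suppression_fraction_min_bs``, artifact
    bounds) are this package's documented operationalizations.
    """

    low_voltage_max: float = 20.0  # uV peak-to-peak
    suppression_max: float = 10.0  # uV peak-to-peak
    suppression_min_dur: float = 1.0  # s
    burst_min_dur: float = 0.5  # s
    burst_min_phases: int = 3
    continuity_freq_split: float = 8.0  # Hz
    isoelectric_max: float = 2.0  # uV peak-to-peak; no clinical number exists
    identical_corr_min: float = 0.75
    suppression_fraction_min_bs: float = 0.10  # below this the epoch counts as continuous
    envelope_window: float = 0.5  # s
    artifact_amp_max: float = 300.0  # uV; |sample| bound for artifact rejection
    artifact_frac_max: float = 0.20
    identical_max_lag: float = 0.025  # s; onset-alignment search in burst correlation

    def __post_init__(self) -> None:
        if not (0.0 < self.isoelectric_max < self.suppression_max < self.low_voltage_max):
            raise ValueError("need 0 < isoelectric_max < suppression_max < low_voltage_max")
        for name in ("suppression_min_dur", "burst_min_dur", "envelope_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_THRESHOLDS = EEGThresholds()


@dataclass
class Burst:
    """A detected burst: its time extent, phase count and waveform segment."""

    start: float  # s from epoch start
    end: float
    phases: int
    samples: np.ndarray  # the waveform of the loudest channel over the burst

    @property
    def duration(self) -> float:
        return self.end - self.start


def _as_2d(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("epoch data must be a nonempty 1-D or (channels, samples) array")
    return arr


def amplitude_envelope(epoch, window: Optional[float] = None) -> np.ndarray:
    """Sliding peak-to-peak amplitude track, reduced across channels by max.

    Parameters
    ----------
    epoch
        An object with ``data`` (channels x samples) and ``fs``, or handled
        duck-typed by the caller.
    window
        Window length in seconds; defaults to 0.5 s.  Must span at least
        two samples.

    Returns
    -------
    ndarray of shape (n_samples,) with the per-time-point peak-to-peak
    amplitude in uV: within each window the max minus min per channel, then
    the maximum over channels.
    """
    if window is None:
        window = DEFAULT_THRESHOLDS.envelope_window
    data = _as_2d(epoch.data)
    fs = float(epoch.fs)
    if window < 2.0 / fs:
        raise ValueError("envelope window must cover at least two samples")
    size = max(2, int(round(window * fs)))
    hi = maximum_filter1d(data, size=size, axis=1, mode="nearest")
    lo = minimum_filter1d(data, size=size, axis=1, mode="nearest")
    return (hi - lo).max(axis=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open sample index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_suppressions(epoch, thresholds: EEGThresholds = DEFAULT_THRESHOLDS) -> list[tuple[float, float]]:
    """Maximal intervals of suppressed activity.

    A suppression is a run of at least ``suppression_min_dur`` seconds during
    which the amplitude envelope stays below ``suppression_max`` (10 uV).
    Returned as sorted, disjoint (start_s, end_s) pairs.
    """
    env = amplitude_envelope(epoch, thresholds.envelope_window)
    fs = float(epoch.fs)
    min_len = int(round(thresholds.suppression_min_dur * fs))
    out = []
    for i0, i1 in _runs(env < thresholds.suppression_max):
        if i1 - i0 >= min_len:
            out.append((i0 / fs, i1 / fs))
    return out


def _count_phases(segment: np.ndarray, amp: float) -> int:
    """Half-waves: sign-alternating excursions beyond ``amp`` after mean removal.

    Consecutive same-sign excursions are merged, which breaks ties toward
    fewer phases.
    """
    x = segment - segment.mean()
    signs = np.zeros(x.size, dtype=np.int8)
    signs[x > amp] = 1
    signs[x < -amp] = -1
    phases = 0
    prev = 0
    for s in signs:
        if s != 0 and s != prev:
            phases += 1
            prev = s
    return phases


def detect_bursts(epoch, thresholds: EEGThresholds = DEFAULT_THRESHOLDS) -> list[Burst]:
    """Segment bursts: supra-suppression intervals >=0.5 s with >=3 phases.

    A burst is a maximal run where the envelope is at or above the
    suppression bound, lasting at least ``burst_min_dur``, whose waveform
    shows at least ``burst_min_phases`` sign-alternating excursions beyond
    the suppression bound.  Each burst carries the waveform of its
    largest-amplitude channel for similarity scoring.
    """
    data = _as_2d(epoch.data)
    env = amplitude_envelope(epoch, thresholds.envelope_window)
    fs = float(epoch.fs)
    n = data.shape[1]
    min_len = int(round(thresholds.burst_min_dur * fs))
    # a supra-threshold envelope run overstates the activity extent by about
    # half the sliding window on each side; erode to the true burst duration
    half = int(round(thresholds.envelope_window * fs / 2.0))
    bursts: list[Burst] = []
    for i0, i1 in _runs(env >= thresholds.suppression_max):
        if i0 > 0:
            i0 += half
        if i1 < n:
            i1 -= half
        if i1 - i0 < min_len:
            continue
        seg = data[:, i0:i1]
        ch = int(np.argmax(seg.max(axis=1) - seg.min(axis=1)))
        wave = seg[ch]
        phases = _count_phases(wave, thresholds.suppression_max)
        if phases >= thresholds.burst_min_phases:
            bursts.append(Burst(i0 / fs, i1 / fs, phases, wave.copy()))
    return bursts


def identical_burst_score(
    bursts: Sequence[Burst],
    fs: float,
    *,
    window: float = 0.5,
    max_lag: float = DEFAULT_THRESHOLDS.identical_max_lag,
) -> float:
    """Mean pairwise correlation of consecutive bursts' initial waveforms.

    For each consecutive pair, the first ``window`` seconds from burst onset
    are compared by Pearson correlation; onsets are aligned by searching lags
    within ``max_lag`` for the maximal absolute correlation (the signed value
    at that lag is kept, so inverted copies score -1).  The mean over pairs
    is returned; stereotyped ("identical") bursts score near 1, independent
    bursts near 0.
    """
    if len(bursts) < 2:
        raise ValueError("identical-burst scoring needs at least two bursts")
    n = int(round(window * fs))
    lag_max = int(round(max_lag * fs))
    scores = []
    for a, b in zip(bursts[:-1], bursts[1:]):
        m = min(len(a.samples), len(b.samples), n)
        if m < 4:
            continue
        xa = a.samples[:m]
        best = 0.0
        for lag in range(-lag_max, lag_max + 1):
            if lag >= 0:
                xb = b.samples[lag : lag + m]
            else:
                xb = b.samples[: m + lag]
            k = min(len(xa), len(xb))
            if k < 4:
                continue
            u, v = xa[:k] - xa[:k].mean(), xb[:k] - xb[:k].mean()
            denom = np.sqrt((u @ u) * (v @ v))
            if denom == 0:
                continue
            r = float(u @ v / denom)
            if abs(r) > abs(best):
                best = r
        scores.append(best)
    if not scores:
        raise ValueError("no comparable burst pairs")
    return float(np.mean(scores))


def dominant_frequency(
    epoch,
    *,
    fmin: float = 0.5,
    fmax: float = 25.0,
    segment_seconds: float = 4.0,
) -> float:
    """Frequency of the maximal spectral peak in [fmin, fmax].

    Uses an averaged periodogram (4-s segments, 50% overlap) of the
    channel-averaged power spectrum.  Raises on flat signals, for which no
    dominant rhythm exists.
    """
    data = _as_2d(epoch.data)
    fs = float(epoch.fs)
    nper = min(int(round(segment_seconds * fs)), data.shape[1])
    freqs, psd = welch(data, fs=fs, nperseg=nper, noverlap=nper // 2, axis=1)
    spectrum = psd.mean(axis=0)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not band.any() or spectrum[band].max() <= 0 or np.ptp(data) == 0:
        raise ValueError("no spectral peak: signal is flat or band empty")
    return float(freqs[band][int(np.argmax(spectrum[band]))])


def is_artifact(
    epoch,
    thresholds: EEGThresholds = DEFAULT_THRESHOLDS,
    *,
    check_constant: bool = True,
) -> bool:
    """Artifact screen: too many extreme samples, or a dead (constant) channel.

    The constant-channel rule targets disconnected electrodes during epoch
    selection; classification skips it, since a genuinely flat epoch is an
    isoelectric pattern, not an artifact.
    """
    data = _as_2d(epoch.data)
    frac_extreme = float(np.mean(np.abs(data) > thresholds.artifact_amp_max))
    if frac_extreme > thresholds.artifact_frac_max:
        return True
    return check_constant and bool((data.std(axis=1) == 0).any())


def classify_epoch(epoch, thresholds: EEGThresholds = DEFAULT_THRESHOLDS) -> EEGCategory:
    """Classify a 5-minute epoch by the background-pattern decision cascade.

    Order of decisions:

    1. artifact screen fails -> ``unassessable``;
    2. envelope everywhere below the isoelectric bound -> ``isoelectric``;
    3. suppression fraction at least ``suppression_fraction_min_bs`` and at
       least two qualifying bursts -> burst-suppression, split into the
       identical / heterogeneous variants by the burst-correlation score;
    4. envelope everywhere below 20 uV -> ``low_voltage``;
    5. otherwise the pattern is continuous: dominant frequency below 8 Hz
       -> ``continuous_slow``, else ``continuous_normal``.

    Epileptiform patterns are never emitted (no spike detector); simulated
    epileptiform epochs classify by their background, typically continuous.
    """
    if is_artifact(epoch, thresholds, check_constant=False):
        return EEGCategory.UNASSESSABLE
    env = amplitude_envelope(epoch, thresholds.envelope_window)
    if env.max() < thresholds.isoelectric_max:
        return EEGCategory.ISOELECTRIC
    duration = _as_2d(epoch.data).shape[1] / float(epoch.fs)
    suppressions = detect_suppressions(epoch, thresholds)
    supp_frac = sum(t1 - t0 for t0, t1 in suppressions) / duration
    if supp_frac >= thresholds.suppression_fraction_min_bs:
        bursts = detect_bursts(epoch, thresholds)
        if len(bursts) >= 2:
            score = identical_burst_score(
                bursts, float(epoch.fs), max_lag=thresholds.identical_max_lag
            )
            if score >= thresholds.identical_corr_min:
                return EEGCategory.BURST_SUPPRESSION_IDENTICAL
            return EEGCategory.BURST_SUPPRESSION_HETEROGENEOUS
    if env.max() < thresholds.low_voltage_max:
        return EEGCategory.LOW_VOLTAGE
    freq = dominant_frequency(epoch)
    if freq < thresholds.continuity_freq_split:
        return EEGCategory.CONTINUOUS_SLOW
    return EEGCategory.CONTINUOUS_NORMAL


def select_epoch(
    recording,
    target_hour: float,
    seed: int,
    *,
    epoch_seconds: float = 300.0,
    window_hours: float = 1.0,
    n_candidates: int = 20,
    thresholds: EEGThresholds = DEFAULT_THRESHOLDS,
):
    """Randomly select an artifact-free 5-minute epoch near a target hour.

    Mirrors the computer algorithm that drew epochs at 12 and 24 hours after
    arrest: a candidate window of ``epoch_seconds`` is drawn uniformly inside
    +-``window_hours`` around ``target_hour``; candidates failing the
    artifact screen are rejected.  Returns an epoch object (via
    ``recording.extract``) or ``None`` when the recording does not cover the
    window or every candidate is artifact-dominated.
    """
    rng = np.random.default_rng(seed)
    lo = max(target_hour - window_hours, recording.start_hour)
    hi = min(target_hour + window_hours, recording.end_hour) - epoch_seconds / 3600.0
    if hi < lo:
        return None
    for _ in range(n_candidates):
        start = float(rng.uniform(lo, hi)) if hi > lo else lo
        epoch = recording.extract(start, epoch_seconds)
        if not is_artifact(epoch, thresholds):
            return epoch
        if hi == lo:
            break
    return None
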