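"""Synthetic EEG epochs realizing each background-pattern category.

Every generated waveform satisfies the defining thresholds of its label by
construction, giving the classifier a ground-truth fixture: isoelectric
epochs stay below the isoelectric bound, low-voltage epochs are continuous
with peak-to-peak amplitude between the suppression and low-voltage bounds,
burst-suppression epochs alternate multi-phase bursts with >=1 s
suppressions (the "identical" variant reuses one burst realization), and
continuous epochs carry a dominant rhythm below or above 8 Hz.

These are amplitude/frequency caricatures, not physiological EEG: no
reactivity, no spatial structure beyond shared activity plus per-channel
noise, and no artifacts other than a white-noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .eeg_classify import EEGCategory

__all__ = ["EEGEpoch", "Recording", "SimParams", "simulate_epoch", "simulate_recording"]


@dataclass
class EEGEpoch:
    """A fixed-duration sampled EEG segment in microvolts."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: list[str]
    true_label: Optional[EEGCategory] = None
    start_hour: Optional[float] = None  # hours since cardiac arrest, if known

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels must match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Seconds; duration * fs equals the per-channel sample count."""
        return self.n_samples / self.fs


@dataclass
class Recording:
    """A long single- or multi-channel signal anchored at cardiac arrest (t=0 h)."""

    data: np.ndarray
    fs: float
    channels: list[str]
    start_hour: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def end_hour(self) -> float:
        return self.start_hour + self.data.shape[1] / self.fs / 3600.0

    def extract(self, start_hour: float, duration_s: float) -> EEGEpoch:
        """Cut an epoch starting at an absolute hour since arrest."""
        if start_hour < self.start_hour - 1e-9 or start_hour * 3600 + duration_s > self.end_hour * 3600 + 1e-6:
            raise ValueError("requested window not covered by the recording")
        i0 = int(round((start_hour - self.start_hour) * 3600.0 * self.fs))
        n = int(round(duration_s * self.fs))
        return EEGEpoch(self.data[:, i0 : i0 + n], self.fs, list(self.channels), start_hour=start_hour)


@dataclass(frozen=True)
class SimParams:
    """Waveform parameters of the epoch generator.

    Amplitudes are peak-to-peak in microvolts and chosen to sit comfortably
    inside the defining bands of each category (e.g. low-voltage at 14 uV,
    between the 10 uV suppression bound and the 20 uV low-voltage bound).
    Durations are seconds.
    """

    fs: float = 256.0
    duration: float = 300.0  # standard epoch length: 5 minutes
    n_channels: int = 1
    noise_floor_uv: float = 0.5  # half-range of the uniform noise floor
    iso_pp: float = 1.2  # isoelectric peak-to-peak budget (< 2 uV bound)
    low_voltage_pp: float = 14.0
    low_voltage_freq: float = 6.0
    continuous_pp: float = 50.0
    slow_freq: float = 4.0
    normal_freq: float = 10.0
    burst_pp: float = 120.0
    burst_dur: tuple[float, float] = (0.7, 1.5)  # >= 0.5 s by definition
    identical_burst_dur: float = 1.0
    suppression_dur: tuple[float, float] = (2.0, 4.0)  # >= 1 s by definition
    suppression_pp: float = 4.0
    burst_band: tuple[float, float] = (1.0, 12.0)  # Hz, band of burst content
    epileptiform_rate: float = 2.0  # discharges per second

    def __post_init__(self) -> None:
        if self.burst_dur[0] < 0.5:
            raise ValueError("bursts must last at least 0.5 s")
        if self.suppression_dur[0] < 1.0:
            raise ValueError("suppressions must last at least 1 s")
        if self.iso_pp < 0 or self.low_voltage_pp < 0 or self.burst_pp < 0:
            raise ValueError("amplitudes must be nonnegative")


DEFAULT_SIM = SimParams()


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """White noise band-limited by FFT masking, unit peak-to-peak."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    y = np.fft.irfft(spec, n)
    ptp = np.ptp(y)
    return y / ptp if ptp > 0 else y


def _tukey(n: int, alpha: float = 0.4) -> np.ndarray:
    from scipy.signal.windows import tukey

    return tukey(n, alpha)


def _burst_template(dur: float, pp: float, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    n = max(int(round(dur * fs)), 8)
    wave = _bandlimited_noise(n, fs, band, rng) * _tukey(n)
    ptp = np.ptp(wave)
    return wave / ptp * pp if ptp > 0 else wave


def _single_channel(label: EEGCategory, p: SimParams, rng: np.random.Generator) -> np.ndarray:
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs
    noise = rng.uniform(-p.noise_floor_uv, p.noise_floor_uv, n)

    if label == EEGCategory.ISOELECTRIC:
        return rng.uniform(-p.iso_pp / 2, p.iso_pp / 2, n)

    if label == EEGCategory.LOW_VOLTAGE:
        am = 1.0 + 0.08 * np.sin(2 * np.pi * 0.07 * t + rng.uniform(0, 2 * np.pi))
        x = np.sin(2 * np.pi * p.low_voltage_freq * t + rng.uniform(0, 2 * np.pi)) * am
        return x * (p.low_voltage_pp / 2) / 1.08 + noise

    if label in (EEGCategory.CONTINUOUS_SLOW, EEGCategory.CONTINUOUS_NORMAL):
        freq = p.slow_freq if label == EEGCategory.CONTINUOUS_SLOW else p.normal_freq
        am = 1.0 + 0.15 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
        x = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)) * am
        x = x * (p.continuous_pp / 2) / 1.15
        return x + rng.standard_normal(n) * p.continuous_pp / 40 + noise

    if label == EEGCategory.EPILEPTIFORM:
        # periodic stereotyped discharges on a suppressed-to-low background;
        # label-only fixture, never emitted by the classifier
        period = int(round(p.fs / p.epileptiform_rate))
        spike = _burst_template(0.25, p.burst_pp * 0.8, p.fs, (2.0, 15.0), rng)
        x = np.zeros(n)
        for start in range(0, n - len(spike), period):
            x[start : start + len(spike)] += spike
        return x + noise

    if label in (EEGCategory.BURST_SUPPRESSION_IDENTICAL, EEGCategory.BURST_SUPPRESSION_HETEROGENEOUS):
        identical = label == EEGCategory.BURST_SUPPRESSION_IDENTICAL
        x = rng.uniform(-p.suppression_pp / 2, p.suppression_pp / 2, n)
        template = _burst_template(p.identical_burst_dur, p.burst_pp, p.fs, p.burst_band, rng)
        pos = int(round(rng.uniform(*p.suppression_dur) * p.fs))
        while pos < n:
            if identical:
                burst = template  # one realization reused: sub-millisecond jitter
            else:
                dur = rng.uniform(*p.burst_dur)
                burst = _burst_template(dur, p.burst_pp * rng.uniform(0.7, 1.3), p.fs, p.burst_band, rng)
            end = min(pos + len(burst), n)
            x[pos:end] = burst[: end - pos]
            pos = end + int(round(rng.uniform(*p.suppression_dur) * p.fs))
        return x

    raise ValueError(f"unknown EEG category: {label!r}")


def simulate_epoch(
    label: EEGCategory | str,
    params: SimParams = DEFAULT_SIM,
    seed: int = 0,
) -> EEGEpoch:
    """Generate one epoch whose waveform satisfies its label's definition.

    Multi-channel epochs share the base activity with an independent noise
    floor per channel, so cross-channel reductions in the classifier see a
    coherent pattern.
    """
    label = EEGCategory(label)
    if label == EEGCategory.UNASSESSABLE:
        raise ValueError("cannot simulate the 'unassessable' pseudo-category")
    rng = np.random.default_rng(seed)
    base = _single_channel(label, params, rng)
    n = base.size
    chans = []
    for _ in range(params.n_channels):
        chans.append(base + rng.uniform(-params.noise_floor_uv, params.noise_floor_uv, n) * 0.5)
    names = [f"ch{i+1}" for i in range(params.n_channels)]
    return EEGEpoch(np.vstack(chans), params.fs, names, true_label=label)


def simulate_recording(
    timeline: Sequence[tuple[float, float, EEGCategory | str]],
    params: SimParams = DEFAULT_SIM,
    seed: int = 0,
) -> Recording:
    """Concatenate labelled segments into a recording anchored at arrest.

    ``timeline`` is a sorted sequence of (start_hour, end_hour, label)
    segments; overlap is an error, gaps are filled with isoelectric-grade
    noise.  The time axis is absolute: hour 0 is the cardiac arrest.
    """
    if not timeline:
        raise ValueError("timeline must contain at least one segment")
    segs = sorted(timeline, key=lambda s: s[0])
    for (s0, e0, _), (s1, _, _) in zip(segs[:-1], segs[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError("timeline segments overlap")
    for s0, e0, _ in segs:
        if e0 <= s0:
            raise ValueError("segment end must exceed its start")
    rng = np.random.default_rng(seed)
    fs = params.fs
    start_hour = segs[0][0]
    total_s = (segs[-1][1] - start_hour) * 3600.0
    n = int(round(total_s * fs))
    data = rng.uniform(-params.iso_pp / 2, params.iso_pp / 2, n)  # gap filler
    for s0, e0, label in segs:
        seg_params = SimParams(**{**params.__dict__, "duration": (e0 - s0) * 3600.0, "n_channels": 1})
        seg = _single_channel(EEGCategory(label), seg_params, rng)
        i0 = int(round((s0 - start_hour) * 3600.0 * fs))
        data[i0 : i0 + seg.size] = seg[: n - i0]
    return Recording(data, fs, ["ch1"], start_hour)
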