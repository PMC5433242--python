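"""Classifier primitives against constructed signals and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eegprog.eeg_classify import (
    Burst,
    EEGCategory,
    EEGThresholds,
    PrognosticGroup,
    amplitude_envelope,
    classify_epoch,
    detect_bursts,
    detect_suppressions,
    dominant_frequency,
    identical_burst_score,
    is_artifact,
    prognostic_group,
    select_epoch,
)
from eegprog.eeg_sim import EEGEpoch, SimParams, simulate_epoch, simulate_recording

THR = EEGThresholds()


def epoch_from(x, fs=64.0):
    return EEGEpoch(np.asarray(x, dtype=float), fs, ["ch1"] if np.ndim(x) == 1 else [f"ch{i+1}" for i in range(len(x))])


def brute_force_envelope(data, fs, window):
    """Per-sample window peak-to-peak by direct scan (independent oracle)."""
    data = np.atleast_2d(data)
    size = max(2, int(round(window * fs)))
    n = data.shape[1]
    out = np.empty(n)
    # window placement matching a centered sliding filter with edge clamping
    left = size // 2
    right = size - 1 - left
    for i in range(n):
        idx = np.clip(np.arange(i - left, i + right + 1), 0, n - 1)
        seg = data[:, idx]
        out[i] = (seg.max(axis=1) - seg.min(axis=1)).max()
    return out


def brute_force_suppressions(data, fs, thr=THR):
    env = brute_force_envelope(data, fs, thr.envelope_window)
    min_len = int(round(thr.suppression_min_dur * fs))
    intervals, start = [], None
    for i, v in enumerate(np.append(env < thr.suppression_max, False)):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                intervals.append((start / fs, i / fs))
            start = None
    return intervals


class TestAmplitudeEnvelope:
    def test_constant_zero_signal(self):
        env = amplitude_envelope(epoch_from(np.zeros(256)), 0.5)
        assert np.all(env == 0.0)

    def test_sine_peak_to_peak(self):
        t = np.arange(0, 4, 1 / 256)
        ep = epoch_from(25.0 * np.sin(2 * np.pi * 10 * t), fs=256.0)
        env = amplitude_envelope(ep, 0.5)
        steady = env[256:-256]
        assert steady == pytest.approx(50.0, rel=0.01)

    def test_max_across_channels(self):
        t = np.arange(0, 2, 1 / 64)
        ep = epoch_from([np.zeros(t.size), 15.0 * np.sin(2 * np.pi * 5 * t)], fs=64.0)
        env = amplitude_envelope(ep, 0.5)
        assert env[32:-32] == pytest.approx(30.0, rel=0.02)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 20, 5 * 64)
        env = amplitude_envelope(epoch_from(x, fs=64.0), 0.5)
        np.testing.assert_allclose(env, brute_force_envelope(x, 64.0, 0.5))

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            amplitude_envelope(epoch_from(np.zeros(64)), window=1 / 128)


class TestDetectSuppressions:
    @staticmethod
    def flanked(quiet_seconds, fs=64.0):
        t_active = np.arange(0, 3, 1 / fs)
        loud = 15.0 * np.sin(2 * np.pi * 6 * t_active)
        quiet = np.full(int(quiet_seconds * fs), 2.5)
        quiet[::2] = -2.5  # 5 uV p-p dither, below the 10 uV bound
        return epoch_from(np.concatenate([loud, quiet, loud]), fs=fs)

    def test_two_second_quiet_interval_found(self):
        supp = detect_suppressions(self.flanked(2.0))
        assert len(supp) == 1
        t0, t1 = supp[0]
        assert (t1 - t0) == pytest.approx(2.0, abs=0.6)  # eroded by the 0.5-s window

    def test_interval_shorter_than_one_second_ignored(self):
        assert detect_suppressions(self.flanked(0.8)) == []

    def test_all_zero_epoch_is_one_full_interval(self):
        ep = epoch_from(np.zeros(5 * 64))
        assert detect_suppressions(ep) == [(0.0, 5.0)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_toy_signals(self, seed):
        rng = np.random.default_rng(seed)
        # piecewise loud/quiet signal, <=10 s at 64 Hz
        segs = []
        for _ in range(6):
            dur = rng.uniform(0.4, 2.0)
            n = int(dur * 64)
            if rng.random() < 0.5:
                segs.append(rng.uniform(-3, 3, n))
            else:
                segs.append(30 * np.sin(2 * np.pi * 5 * np.arange(n) / 64))
        x = np.concatenate(segs)[: 10 * 64]
        ep = epoch_from(x, fs=64.0)
        assert detect_suppressions(ep) == brute_force_suppressions(x, 64.0)

    def test_raising_threshold_only_extends_intervals(self):
        # monotonicity: a larger suppression bound can only lengthen/merge
        ep = self.flanked(2.0)
        small = detect_suppressions(ep, EEGThresholds(suppression_max=8.0))
        large = detect_suppressions(ep, EEGThresholds(suppression_max=12.0))
        total_small = sum(t1 - t0 for t0, t1 in small)
        total_large = sum(t1 - t0 for t0, t1 in large)
        assert total_large >= total_small
        for t0, t1 in small:
            assert any(u0 <= t0 and t1 <= u1 for u0, u1 in large)


class TestDetectBursts:
    @staticmethod
    def burst_between_suppressions(burst_dur, freq=4.0, amp=40.0, fs=64.0):
        quiet = np.zeros(int(2 * fs))
        t = np.arange(0, burst_dur, 1 / fs)
        burst = amp * np.sin(2 * np.pi * freq * t)
        return epoch_from(np.concatenate([quiet, burst, quiet]), fs=fs)

    def test_eight_phase_burst_detected(self):
        ep = self.burst_between_suppressions(1.0, freq=4.0)
        bursts = detect_bursts(ep)
        assert len(bursts) == 1
        assert bursts[0].phases == 8

    def test_sub_500ms_blip_is_not_a_burst(self):
        ep = self.burst_between_suppressions(0.3, freq=10.0)
        assert detect_bursts(ep) == []

    def test_monophasic_hump_is_not_a_burst(self):
        fs = 64.0
        quiet = np.zeros(int(2 * fs))
        t = np.arange(0, 0.6, 1 / fs)
        hump = 40.0 * np.sin(np.pi * t / 0.6)  # single positive excursion
        ep = epoch_from(np.concatenate([quiet, hump, quiet]), fs=fs)
        assert detect_bursts(ep) == []


class TestIdenticalBurstScore:
    @staticmethod
    def as_bursts(waves, fs=64.0):
        t = 0.0
        out = []
        for w in waves:
            out.append(Burst(t, t + len(w) / fs, 5, np.asarray(w, float)))
            t += len(w) / fs + 2.0
        return out

    def test_exact_copies_score_one(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 30, 64)
        score = identical_burst_score(self.as_bursts([w, w.copy(), w.copy()]), fs=64.0)
        assert score == pytest.approx(1.0)

    def test_polarity_flip_scores_minus_one(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 30, 64)
        score = identical_burst_score(self.as_bursts([w, -w]), fs=64.0)
        assert score == pytest.approx(-1.0)

    def test_independent_bursts_score_near_zero(self):
        # Monte-Carlo: mean score over 20 seeds of random burst pairs
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            waves = [rng.normal(0, 30, 64) for _ in range(6)]
            scores.append(identical_burst_score(self.as_bursts(waves), fs=64.0))
        assert abs(np.mean(scores)) < 0.3

    def test_fewer_than_two_bursts_rejected(self):
        with pytest.raises(ValueError):
            identical_burst_score(self.as_bursts([np.ones(64)]), fs=64.0)


class TestDominantFrequency:
    @pytest.mark.parametrize("freq", [4.0, 10.0])
    def test_pure_sine(self, freq):
        t = np.arange(0, 20, 1 / 128)
        ep = epoch_from(np.sin(2 * np.pi * freq * t), fs=128.0)
        assert dominant_frequency(ep) == pytest.approx(freq, abs=0.5)

    def test_mixture_dominated_by_larger_component(self):
        t = np.arange(0, 20, 1 / 128)
        x = 3.0 * np.sin(2 * np.pi * 4 * t) + 1.0 * np.sin(2 * np.pi * 10 * t)
        assert dominant_frequency(epoch_from(x, fs=128.0)) == pytest.approx(4.0, abs=0.5)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(epoch_from(np.zeros(1024), fs=128.0))


class TestClassifyEpoch:
    def test_zero_signal_is_isoelectric(self):
        assert classify_epoch(epoch_from(np.zeros(30 * 64))) == EEGCategory.ISOELECTRIC

    def test_continuous_15uv_activity_is_low_voltage(self):
        t = np.arange(0, 30, 1 / 64)
        ep = epoch_from(7.5 * np.sin(2 * np.pi * 6 * t), fs=64.0)
        assert classify_epoch(ep) == EEGCategory.LOW_VOLTAGE

    def test_simulated_identical_burst_suppression_recovered(self):
        ep = simulate_epoch("burst_suppression_identical", SimParams(duration=60.0), seed=1)
        assert classify_epoch(ep) == EEGCategory.BURST_SUPPRESSION_IDENTICAL

    def test_artifact_dominated_epoch_unassessable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 500, 30 * 64)  # most samples beyond +-300 uV
        assert classify_epoch(epoch_from(x)) == EEGCategory.UNASSESSABLE


class TestPrognosticGroup:
    @pytest.mark.parametrize(
        "category,group",
        [
            ("isoelectric", PrognosticGroup.UNFAVORABLE),
            ("low_voltage", PrognosticGroup.UNFAVORABLE),
            ("burst_suppression_identical", PrognosticGroup.UNFAVORABLE),
            ("epileptiform", PrognosticGroup.INTERMEDIATE),
            ("burst_suppression_heterogeneous", PrognosticGroup.INTERMEDIATE),
            ("continuous_slow", PrognosticGroup.FAVORABLE),
            ("continuous_normal", PrognosticGroup.FAVORABLE),
            ("unassessable", PrognosticGroup.UNASSESSABLE),
        ],
    )
    def test_fixed_mapping(self, category, group):
        assert prognostic_group(category) == group

    def test_total_and_surjective(self):
        groups = {prognostic_group(c) for c in EEGCategory}
        assert {
            PrognosticGroup.UNFAVORABLE,
            PrognosticGroup.INTERMEDIATE,
            PrognosticGroup.FAVORABLE,
        } <= groups


class TestSelectEpoch:
    def test_recording_started_after_target_gives_none(self):
        rec = simulate_recording([(14.0, 14.5, "continuous_normal")], SimParams(fs=64.0), seed=0)
        assert select_epoch(rec, target_hour=12.0, seed=0) is None

    def test_epoch_drawn_inside_the_window(self):
        rec = simulate_recording([(11.0, 13.0, "continuous_normal")], SimParams(fs=32.0), seed=0)
        ep = select_epoch(rec, target_hour=12.0, seed=0)
        assert ep is not None
        assert 11.0 <= ep.start_hour
        assert ep.start_hour + 300.0 / 3600.0 <= 13.0
        assert ep.duration == pytest.approx(300.0)

    def test_all_artifact_window_gives_none(self):
        fs = 32.0
        n = int(0.5 * 3600 * fs)
        rng = np.random.default_rng(0)
        from eegprog.eeg_sim import Recording

        rec = Recording(rng.normal(0, 500, n), fs, ["ch1"], start_hour=11.8)
        assert select_epoch(rec, target_hour=12.0, seed=0) is None
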