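"""Windowing, filtering, autocorrelation and repetition-segmentation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabsense.preprocess import (GravityBodyPair, RecordingTooShortError,
                                   SegmentationError, SensorWindow,
                                   SignalRecording, autocorrelation,
                                   autocorrelation_sequence,
                                   denoise_normalize, gravity_body_split,
                                   segment_repetitions, sliding_windows)


def make_rec(acc, fs=32.0, **kw):
    acc = np.asarray(acc, dtype=float)
    return SignalRecording(t=np.arange(len(acc)) / fs, acc=acc, **kw)


class TestSlidingWindows:
    @pytest.mark.parametrize("T,size,overlap,starts", [
        (200, 80, 0.5, [0, 40, 80, 120]),
        (80, 80, 0.5, [0]),
        (80, 80, 0.0, [0]),
        (160, 80, 0.0, [0, 80]),
    ])
    def test_window_starts(self, T, size, overlap, starts):
        rec = make_rec(np.zeros((T, 3)))
        wins = sliding_windows(rec, size=size, overlap=overlap)
        assert [w.origin[1] for w in wins] == starts
        assert all(w.window_size == size for w in wins)

    def test_window_count_formula(self):
        for T in (80, 95, 200, 333):
            rec = make_rec(np.zeros((T, 3)))
            wins = sliding_windows(rec, size=80, overlap=0.5)
            stride = 40
            assert len(wins) == (T - 80) // stride + 1

    def test_too_short_recording_raises(self):
        rec = make_rec(np.zeros((79, 3)))
        with pytest.raises(RecordingTooShortError):
            sliding_windows(rec, size=80)

    def test_invalid_overlap(self):
        rec = make_rec(np.zeros((100, 3)))
        with pytest.raises(ValueError):
            sliding_windows(rec, size=80, overlap=1.0)


class TestDenoiseNormalize:
    def test_spike_removed_and_scaled(self):
        axis = np.array([0.0, 10.0, 0.0, 0.0, 0.0])
        win = SensorWindow(np.stack([axis] * 3, axis=1))
        out = denoise_normalize(win, median_size=3)
        # size-3 median with replicated edges removes the lone spike
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert np.all(out.values[1] < 1.0)  # spike gone

    def test_constant_axis_maps_to_half(self):
        win = SensorWindow(np.full((4, 3), 5.0))
        out = denoise_normalize(win)
        assert np.allclose(out.values, 0.5)

    def test_monotone_ramp_keeps_order_and_range(self):
        ramp = np.linspace(0, 1, 20)
        win = SensorWindow(np.stack([ramp, ramp[::-1], ramp], axis=1))
        out = denoise_normalize(win)
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        assert np.all(np.diff(out.values[:, 0]) >= 0)

    def test_second_normalization_is_identity(self):
        rng = np.random.default_rng(0)
        win = SensorWindow(rng.normal(size=(50, 3)))
        once = denoise_normalize(win)
        lo, hi = once.values.min(axis=0), once.values.max(axis=0)
        again = (once.values - lo) / (hi - lo)
        assert np.allclose(again, once.values)

    def test_even_median_size_rejected(self):
        with pytest.raises(ValueError):
            denoise_normalize(SensorWindow(np.zeros((5, 3))), median_size=4)


class TestGravityBodySplit:
    def test_dc_goes_to_gravity(self):
        win = SensorWindow(np.tile([0.0, 0.0, 1.0], (80, 1)))
        pair = gravity_body_split(win, cutoff=0.3, fs=32.0)
        assert np.allclose(pair.gravity, win.values, atol=1e-6)
        assert np.allclose(pair.body, 0.0, atol=1e-6)

    def test_fast_sine_goes_to_body(self):
        t = np.arange(160) / 32.0
        sine = np.sin(2 * np.pi * 8.0 * t)  # 8 Hz >> 0.3 Hz cutoff
        win = SensorWindow(np.stack([sine] * 3, axis=1))
        pair = gravity_body_split(win, cutoff=0.3, fs=32.0)
        assert np.abs(pair.gravity).max() < 0.05
        assert np.allclose(pair.body, win.values - pair.gravity)

    def test_mixture_recovered_within_5pct_rms(self):
        t = np.arange(320) / 32.0
        dc = 0.8
        fast = 0.5 * np.sin(2 * np.pi * 5.0 * t)
        win = SensorWindow(np.stack([dc + fast] * 3, axis=1))
        pair = gravity_body_split(win, cutoff=0.3, fs=32.0)
        rms = lambda x: np.sqrt(np.mean(x ** 2))
        assert rms(pair.gravity[:, 0] - dc) / rms(np.full_like(t, dc)) < 0.05
        assert rms(pair.body[:, 0] - fast) / rms(fast) < 0.05

    def test_reconstruction_exact(self):
        rng = np.random.default_rng(1)
        win = SensorWindow(rng.normal(size=(100, 3)))
        pair = gravity_body_split(win, fs=32.0)
        assert np.allclose(pair.gravity + pair.body, win.values)

    def test_invalid_cutoff(self):
        win = SensorWindow(np.zeros((80, 3)))
        with pytest.raises(ValueError):
            gravity_body_split(win, cutoff=20.0, fs=32.0)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        assert autocorrelation(x, 0) == pytest.approx(1.0)

    def test_periodic_signal_peaks_at_period(self):
        # the estimator averages the lagged product over the full length T,
        # so a pure sine at lag P approaches (T-P)/T from below
        P = 40
        x = np.sin(2 * np.pi * np.arange(20 * P) / P)
        assert autocorrelation(x, P) > 0.9
        x5 = np.sin(2 * np.pi * np.arange(5 * P) / P)
        assert autocorrelation(x5, P) > 0.75

    def test_white_noise_small_at_large_lag(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        assert abs(autocorrelation(x, 97)) < 0.2

    def test_constant_series_raises(self):
        with pytest.raises(ZeroDivisionError):
            autocorrelation(np.ones(50), 1)

    def test_sequence_matches_scalar_definition(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=64)
        seq = autocorrelation_sequence(x)
        for k in (0, 1, 5, 31, 63):
            assert seq[k] == pytest.approx(autocorrelation(x, k))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        x = np.random.default_rng(seed).normal(size=128)
        seq = autocorrelation_sequence(x)
        assert np.all(seq <= 1.0 + 1e-12) and np.all(seq >= -1.0 - 1e-12)


def bump_train(n_reps=10, period=80, jitter=0.0, rng=None):
    """Synthetic train of Gaussian bumps with optional spacing jitter;
    returns (signal (T,3), true bump centers)."""
    rng = rng or np.random.default_rng(0)
    parts, centers, pos = [], [], 0
    for _ in range(n_reps):
        p = int(round(period * (1 + rng.uniform(-jitter, jitter))))
        tau = (np.arange(p) + 0.5) / p
        bump = np.exp(-0.5 * ((tau - 0.5) / 0.08) ** 2)
        parts.append(np.stack([bump, 0.5 * bump, np.zeros(p)], axis=1))
        centers.append(pos + p // 2)
        pos += p
    return np.concatenate(parts, axis=0), centers


class TestSegmentRepetitions:
    def test_identical_bumps_equal_segments(self):
        sig, centers = bump_train(jitter=0.0)
        res = segment_repetitions(make_rec(sig), n_reps=10)
        assert len(res.segments) == 10
        gaps = np.diff(res.boundaries)
        assert np.var(gaps) < 4.0  # near-equal split

    def test_jittered_bumps_one_per_segment(self):
        rng = np.random.default_rng(5)
        sig, centers = bump_train(jitter=0.05, rng=rng)
        res = segment_repetitions(make_rec(sig), n_reps=10)
        for i, c in enumerate(centers):
            assert res.boundaries[i] <= c < res.boundaries[i + 1]

    def test_boundary_recovery_within_10pct_of_period(self):
        sig, _ = bump_train(jitter=0.0, period=80)
        res = segment_repetitions(make_rec(sig), n_reps=10)
        true = np.arange(11) * 80
        assert np.all(np.abs(res.boundaries - true) <= 8)

    def test_constant_signal_raises(self):
        rec = make_rec(np.ones((400, 3)))
        with pytest.raises(SegmentationError):
            segment_repetitions(rec, n_reps=10)

    def test_segments_partition_without_overlap(self):
        sig, _ = bump_train()
        res = segment_repetitions(make_rec(sig), n_reps=10)
        assert sum(len(s) for s in res.segments) == len(sig)
        assert np.all(np.diff(res.boundaries) > 0)


class TestSignalRecordingInvariants:
    def test_rejects_nonmonotone_time(self):
        with pytest.raises(ValueError):
            SignalRecording(t=np.array([0.0, 0.0, 1.0]), acc=np.zeros((3, 3)))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            SignalRecording(t=np.arange(4.0), acc=np.zeros((3, 3)))
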