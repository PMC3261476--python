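import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pulsecam as pc


def series(v, fps=20.0):
    v = np.asarray(v, dtype=float)
    return pc.SampleSeries(np.arange(len(v)) / fps, v, fps)


class TestDetrend:
    def test_constant_series_becomes_zero(self):
        out = pc.detrend(series(np.full(100, 7.0)), window=1.5)
        assert np.allclose(out.v, 0.0)

    def test_linear_ramp_interior_is_zero(self):
        out = pc.detrend(series(np.arange(200.0)), window=1.5)
        w = 31  # 1.5 s at 20 fps, rounded odd
        assert np.allclose(out.v[w:-w], 0.0, atol=1e-9)

    def test_recovers_sinusoid_under_linear_drift(self):
        t = np.arange(600) / 20.0
        pure = np.sin(2 * np.pi * 1.2 * t)
        drift = 0.5 * t
        out = pc.detrend(series(pure + drift), window=1.5)
        interior = slice(40, -40)
        r = np.corrcoef(out.v[interior], pure[interior])[0, 1]
        assert r > 0.99

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(pc.EmptyInputError):
            pc.detrend(series(np.zeros(10)), window=5.0)


class TestBandpass:
    def test_inband_sinusoid_passes_with_unit_gain(self):
        t = np.arange(1200) / 20.0
        out = pc.bandpass(series(np.sin(2 * np.pi * 1.2 * t)), 0.67, 3.0)
        steady = out.v[200:-200]
        amp = (steady.max() - steady.min()) / 2
        assert 0.9 <= amp <= 1.1

    def test_slow_drift_is_suppressed(self):
        t = np.arange(1200) / 20.0
        out = pc.bandpass(series(np.sin(2 * np.pi * 0.05 * t)), 0.67, 3.0)
        assert np.abs(out.v[200:-200]).max() < 0.1

    def test_zero_series_stays_zero(self):
        out = pc.bandpass(series(np.zeros(100)), 0.67, 3.0)
        assert np.allclose(out.v, 0.0)

    @pytest.mark.parametrize("lo,hi", [(0.0, 3.0), (3.0, 0.67), (0.67, 11.0)])
    def test_invalid_band_rejected(self, lo, hi):
        with pytest.raises(pc.ConfigurationError):
            pc.bandpass(series(np.zeros(100)), lo, hi)


class TestDetectBeats:
    def test_sixty_seconds_at_72bpm_yields_72_beats(self):
        t = np.arange(1200) / 20.0
        s = series(np.sin(2 * np.pi * 1.2 * t))
        beats = pc.detect_beats(s)
        assert abs(len(beats) - 72) <= 1

    def test_beat_intervals_have_subframe_accuracy(self):
        # a 1 Hz sinusoid has peaks exactly 1 s apart; parabolic
        # interpolation must beat the 50 ms frame grid by a wide margin
        t = np.arange(600) / 20.0
        beats = pc.detect_beats(series(np.sin(2 * np.pi * t)))
        intervals = np.diff(beats.times)
        assert np.abs(intervals - 1.0).max() < 0.01

    def test_all_false_mask_yields_no_beats(self):
        t = np.arange(200) / 20.0
        s = series(np.sin(2 * np.pi * 1.2 * t))
        assert len(pc.detect_beats(s, quality_mask=np.zeros(200, bool))) == 0

    def test_refractory_keeps_only_the_more_prominent_of_close_peaks(self):
        # two Gaussian bumps 0.2 s apart (< 0.33 s refractory): brute-force
        # enumeration says samples 100 and 104 are both local maxima; only
        # the taller may survive
        t = np.arange(400) / 20.0
        v = 1.0 * np.exp(-((t - 5.0) ** 2) / (2 * 0.05**2))
        v += 0.6 * np.exp(-((t - 5.2) ** 2) / (2 * 0.05**2))
        local_maxima = [
            i for i in range(1, 399) if v[i - 1] < v[i] > v[i + 1] and v[i] > 0.1
        ]
        assert len(local_maxima) == 2
        beats = pc.detect_beats(series(v))
        near = beats.times[(beats.times > 4.5) & (beats.times < 5.7)]
        assert len(near) == 1
        assert abs(near[0] - 5.0) < 0.1

    def test_under_two_seconds_is_insufficient_signal(self):
        with pytest.raises(pc.InsufficientSignalError):
            pc.detect_beats(series(np.zeros(30)))


class TestRollingHR:
    def test_unit_intervals_give_60bpm_at_t4(self):
        hr = pc.rolling_hr(pc.BeatSeries(np.arange(5.0)), k=4)
        assert len(hr) == 1
        assert hr.t[0] == 4.0 and hr.hr[0] == pytest.approx(60.0)

    def test_three_quarter_second_beats_give_80bpm(self):
        beats = pc.BeatSeries(np.arange(8) * 0.75)
        hr = pc.rolling_hr(beats, k=4)
        assert np.allclose(hr.hr, 80.0)

    def test_matches_independent_window_oracle_on_jittered_beats(self, rng):
        times = np.cumsum(0.8 + rng.normal(0, 0.03, size=50))
        hr = pc.rolling_hr(pc.BeatSeries(times), k=4)
        oracle = [60.0 * 4 / (times[i] - times[i - 4]) for i in range(4, 50)]
        assert np.allclose(hr.hr, oracle)
        assert np.allclose(hr.t, times[4:])

    def test_too_few_beats_rejected(self):
        with pytest.raises(pc.InsufficientBeatsError):
            pc.rolling_hr(pc.BeatSeries(np.arange(4.0)), k=4)

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(0.5, 2.0), seed=st.integers(0, 2**16))
    def test_time_scaling_beats_scales_hr_inversely(self, c, seed):
        rng = np.random.default_rng(seed)
        times = np.cumsum(0.7 + rng.uniform(0, 0.3, size=20))
        base = pc.rolling_hr(pc.BeatSeries(times), k=4)
        scaled = pc.rolling_hr(pc.BeatSeries(times * c), k=4)
        assert np.allclose(scaled.hr, base.hr / c)


class TestPerSecondHR:
    def test_constant_rolling_hr_holds_everywhere(self):
        hr = pc.rolling_hr(pc.BeatSeries(np.arange(12.0)), k=4)
        sec = pc.per_second_hr(hr, 10.0)
        assert np.allclose(sec.hr[sec.quality], 60.0)

    def test_seconds_before_first_window_are_flagged(self):
        # first beat window completes at the 5th beat, t = 5.6 s
        beats = pc.BeatSeries(1.6 + np.arange(10.0))
        sec = pc.per_second_hr(pc.rolling_hr(beats, k=4), 10.0)
        assert not sec.quality[:5].any()
        assert sec.quality[5:].all()

    def test_step_change_appears_after_window_completes(self):
        # 60 bpm for 30 s then 80 bpm: hand-simulated schedule says the
        # per-second trace first departs from 60 at the second following
        # completion of the first window containing a short interval
        t1 = np.arange(0.0, 30.5, 1.0)
        t2 = t1[-1] + np.arange(1, 20) * 0.75
        beats = pc.BeatSeries(np.concatenate([t1, t2]))
        sec = pc.per_second_hr(pc.rolling_hr(beats, k=4), 44.0)
        expected_first_change = int(np.floor(t2[0]))  # window ending at first short beat
        changed = np.flatnonzero(~np.isclose(sec.hr, 60.0) & sec.quality)
        assert sec.t[changed[0]] == expected_first_change + 1

    def test_loss_events_mark_seconds_invalid(self):
        hr = pc.rolling_hr(pc.BeatSeries(np.arange(12.0)), k=4)
        sec = pc.per_second_hr(hr, 10.0, [pc.QualityEvent(6.0, 8.0)])
        assert not sec.quality[5:8].any()  # seconds 6, 7, 8


class TestPerMinuteMean:
    def _per_second(self, hr_values, quality=None):
        n = len(hr_values)
        q = np.ones(n, bool) if quality is None else np.asarray(quality, bool)
        return pc.HRSeries(np.arange(1, n + 1, dtype=float), hr_values, q)

    def test_constant_input_is_conserved_exactly(self):
        sec = self._per_second(np.full(300, 72.0))
        out = pc.per_minute_mean(sec, 5)
        assert np.allclose(out.hr, 72.0) and out.quality.all()

    def test_alternating_minute_averages_to_midpoint(self):
        v = np.tile([60.0, 80.0], 30)
        out = pc.per_minute_mean(self._per_second(v), 1)
        assert out.hr[0] == pytest.approx(70.0)

    def test_matches_groupby_minute_oracle(self, rng):
        v = 70 + rng.normal(0, 3, size=300)
        q = rng.random(300) > 0.2
        out = pc.per_minute_mean(self._per_second(v, q), 5)
        for m in range(5):
            sel = q[m * 60 : (m + 1) * 60]
            vals = v[m * 60 : (m + 1) * 60][sel]
            assert out.hr[m] == pytest.approx(vals.mean())
            assert out.quality[m] == (sel.sum() >= 30)

    def test_sparse_minute_flagged_invalid(self):
        q = np.zeros(60, bool)
        q[:10] = True
        out = pc.per_minute_mean(self._per_second(np.full(60, 70.0), q), 1)
        assert not out.quality[0]
        assert out.hr[0] == pytest.approx(70.0)

    def test_no_valid_samples_anywhere_rejected(self):
        sec = self._per_second(np.full(120, 70.0), np.zeros(120, bool))
        with pytest.raises(pc.InsufficientSignalError):
            pc.per_minute_mean(sec, 2)


class TestSignalLossEvents:
    def test_all_true_mask_has_no_events(self):
        assert pc.signal_loss_events(np.ones(100, bool), 20.0) == []

    def test_three_second_gap_maps_to_seconds(self):
        mask = np.ones(400, bool)
        mask[100:160] = False
        events = pc.signal_loss_events(mask, 20.0)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (5.0, 8.0)

    def test_short_gaps_below_min_gap_ignored(self):
        mask = np.ones(100, bool)
        mask[10:20] = False  # 0.5 s < 2 s
        assert pc.signal_loss_events(mask, 20.0) == []

    def test_matches_run_length_encoding_oracle(self, rng):
        mask = rng.random(500) > 0.3
        events = pc.signal_loss_events(mask, 20.0, min_gap=0.25)
        runs = []
        start = None
        for i, ok in enumerate(mask.tolist() + [True]):
            if not ok and start is None:
                start = i
            elif ok and start is not None:
                runs.append((start, i))
                start = None
        expect = [
            (s / 20.0, e / 20.0) for s, e in runs if (e - s) / 20.0 >= 0.25
        ]
        assert [(ev.start, ev.end) for ev in events] == expect

    def test_min_gap_below_frame_period_rejected(self):
        with pytest.raises(pc.ConfigurationError):
            pc.signal_loss_events(np.ones(10, bool), 20.0, min_gap=0.01)


def test_end_to_end_constant_hr_recovery_within_half_bpm():
    # noiseless render of a constant 66 bpm pulse; the full chain must
    # recover the configured HR per minute to within 0.5 bpm
    cfg = pc.BeatGenConfig(mean_hr=66.0, rr_jitter_sd=0.0, modulation_amp=0.0,
                           duration=125.0)
    beats = pc.gen_beat_times(cfg)
    meta = pc.VideoMeta(n_frames=2400)  # 2 min
    render = pc.RenderConfig(pixel_noise_sd=0.0)
    stream = pc.render_frames(beats, meta, render, np.random.default_rng(3))
    s = pc.frames_to_series(stream)
    mask = pc.stream_quality_mask(stream)
    _, _, per_min, _ = pc.analyze_series(s, mask, n_minutes=2)
    assert per_min.quality.all()
    assert np.abs(per_min.hr - 66.0).max() < 0.5


def test_fft_oracle_agrees_with_rolling_hr_on_noisy_stream():
    # constant-HR stream with pixel noise: mean rolling HR within 1 bpm of
    # 60 x the dominant FFT frequency of the extracted series
    cfg = pc.BeatGenConfig(mean_hr=78.0, rr_jitter_sd=0.0, modulation_amp=0.0,
                           duration=125.0)
    beats = pc.gen_beat_times(cfg)
    meta = pc.VideoMeta(n_frames=2400)
    stream = pc.render_frames(beats, meta, pc.RenderConfig(pixel_noise_sd=4.0),
                              np.random.default_rng(11))
    s = pc.frames_to_series(stream)
    mask = pc.stream_quality_mask(stream)
    _, sec, _, _ = pc.analyze_series(s, mask)
    v = s.v - s.v.mean()
    freqs = np.fft.rfftfreq(len(v), d=1.0 / s.fps)
    band = (freqs >= 0.67) & (freqs <= 3.0)
    dom = freqs[band][np.argmax(np.abs(np.fft.rfft(v))[band])]
    assert abs(sec.hr[sec.quality].mean() - 60.0 * dom) <= 1.0
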