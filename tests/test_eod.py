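"""EOD detection, alignment, vectorization and doublet screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulseid.eod import (
    DoubletFlag,
    EodEvent,
    MultichannelRecording,
    PendingReviewError,
    align_and_extract,
    average_waveform,
    build_vector,
    confirm_doublets,
    detect_eods,
    doublet_screen,
    extract_events,
)
from pulseid.synth import make_biphasic_pulse

FS = 125_000.0


def recording_with_pulses(times_s, amps=None, n_channels=7, duration=0.05,
                          noise=0.0, seed=0, width_factor=1.0):
    """Plant biphasic pulses at given times; per-channel amplitude scaling."""
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    samples = rng.normal(0, noise, (n_channels, n)) if noise else np.zeros(
        (n_channels, n))
    template = make_biphasic_pulse(FS, width_factor=width_factor)
    if amps is None:
        amps = np.linspace(1.0, 0.2, n_channels)
    for t in np.atleast_1d(times_s):
        start = int(round(t * FS)) - len(template) // 2
        samples[:, start:start + len(template)] += np.outer(amps, template)
    return MultichannelRecording(samples, FS)


class TestDetection:
    def test_single_pulse_single_event(self):
        rec = recording_with_pulses([0.01])
        events = detect_eods(rec, np.full(7, 0.1))
        assert len(events) == 1

    def test_refractory_keeps_earlier_of_close_pair(self):
        # pulses 300 us apart merge into one event at the earlier time
        # (second pulse weaker so superposition keeps both peaks in place)
        rec = recording_with_pulses([0.010])
        second = recording_with_pulses([0.0103])
        rec = MultichannelRecording(rec.samples + 0.5 * second.samples, FS)
        events = detect_eods(rec, np.full(7, 0.1))
        assert len(events) == 1
        assert abs(events[0] / FS - 0.010) < 300e-6

    def test_pulses_beyond_refractory_both_kept(self):
        rec = recording_with_pulses([0.010, 0.020])
        assert len(detect_eods(rec, np.full(7, 0.1))) == 2

    def test_noise_below_threshold_no_events(self):
        rec = recording_with_pulses([], noise=0.01, seed=3)
        assert len(detect_eods(rec, np.full(7, 0.08))) == 0

    def test_nonpositive_threshold_rejected(self):
        rec = recording_with_pulses([0.01])
        with pytest.raises(ValueError):
            detect_eods(rec, np.zeros(7))

    def test_event_times_strictly_increasing_and_spaced(self):
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(0.005, 0.045, 12))
        rec = recording_with_pulses(times, noise=0.02, seed=4)
        events = detect_eods(rec, np.full(7, 0.15))
        assert np.all(np.diff(events) >= int(round(400e-6 * FS)))


class TestAlignment:
    def test_window_arithmetic_at_125khz(self):
        # 272 us pre / 128 us post at 125 kHz -> 34 + 1 + 16 = 51 samples,
        # flattened over 7 channels -> 357 values
        rec = recording_with_pulses([0.01])
        ev = align_and_extract(rec, int(0.01 * FS) - 5)
        assert ev.pre_samples == 34
        assert ev.post_samples == 16
        assert ev.width == 51
        assert len(build_vector(ev).values) == 357

    def test_alignment_invariant_to_detection_jitter(self):
        rec = recording_with_pulses([0.01])
        peak = int(np.argmax(np.abs(rec.samples).mean(axis=0)))
        windows = [align_and_extract(rec, peak + j).window
                   for j in (-2, -1, 0, 1, 2)]
        for w in windows[1:]:
            np.testing.assert_array_equal(w, windows[0])

    def test_mean_abs_peak_at_pre_samples(self):
        rec = recording_with_pulses([0.01], noise=0.01, seed=5)
        ev = align_and_extract(rec, int(0.01 * FS) - 4)
        assert int(np.argmax(ev.mean_abs_trace())) == ev.pre_samples

    def test_boundary_event_dropped(self):
        # pulse so close to the recording start that the 34-sample
        # pre-window cannot be cut
        rec = recording_with_pulses([0.0002])
        with pytest.raises(IndexError):
            align_and_extract(rec, 5)
        # extract_events drops it quietly
        assert extract_events(rec, [5]) == []


class TestWaveformVector:
    def event(self, **kw):
        rec = recording_with_pulses([0.01], **kw)
        return align_and_extract(rec, int(0.01 * FS))

    def test_max_abs_exactly_one(self):
        vec = build_vector(self.event(noise=0.01, seed=6))
        assert np.max(np.abs(vec.values)) == 1.0

    def test_scale_invariance(self):
        ev = self.event()
        scaled = EodEvent(ev.peak_index, ev.window * 10.0, ev.pre_samples,
                          ev.post_samples, ev.detect_channel)
        np.testing.assert_allclose(build_vector(scaled).values,
                                   build_vector(ev).values, atol=1e-15)

    def test_single_nonzero_channel(self):
        ev = self.event()
        lone = ev.window.copy()
        lone[1:] = 0.0
        ev2 = EodEvent(ev.peak_index, lone, ev.pre_samples, ev.post_samples)
        values = build_vector(ev2).values
        assert np.all(values[51:] == 0)
        assert np.max(np.abs(values[:51])) == 1.0

    def test_all_zero_window_rejected(self):
        ev = self.event()
        zero = EodEvent(ev.peak_index, np.zeros_like(ev.window),
                        ev.pre_samples, ev.post_samples)
        with pytest.raises(ValueError):
            build_vector(zero)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_idempotent_under_renormalization(self, scale):
        ev = self.event()
        once = build_vector(ev).values
        again = build_vector(EodEvent(
            ev.peak_index, (once * scale).reshape(ev.window.shape),
            ev.pre_samples, ev.post_samples)).values
        np.testing.assert_allclose(again, once, atol=1e-12)


class TestAverageWaveform:
    def events(self, times, **kw):
        rec = recording_with_pulses(times, **kw)
        return extract_events(rec, detect_eods(rec, np.full(7, 0.1)))

    def test_identical_events_average_equals_each(self):
        evs = self.events([0.01, 0.02, 0.03])
        avg = average_waveform(evs)
        np.testing.assert_allclose(avg, evs[0].mean_abs_trace(normalize=True),
                                   atol=1e-12)

    def test_peak_is_one(self):
        evs = self.events([0.01, 0.02], noise=0.01, seed=7)
        assert average_waveform(evs).max() == pytest.approx(1.0)

    def test_jittered_average_broader_than_template(self):
        # explicit-averaging oracle: symmetric +/-2-sample jitter broadens
        # the mean trace relative to the jitter-free template
        rec = recording_with_pulses([0.01])
        peak = int(np.argmax(np.abs(rec.samples).mean(axis=0)))
        clean = align_and_extract(rec, peak)
        jittered = []
        for j in (-2, -1, 0, 1, 2):
            w = rec.samples[:, peak + j - 34: peak + j + 17].copy()
            jittered.append(EodEvent(peak + j, w, 34, 16))
        avg_jit = np.mean([e.mean_abs_trace() for e in jittered], axis=0)
        avg_jit /= avg_jit.max()
        template = clean.mean_abs_trace(normalize=True)
        # broader = more mass away from the peak
        assert avg_jit.sum() > template.sum()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_waveform([])


class TestDoubletScreen:
    def test_event_equal_to_average_never_flagged(self):
        rec = recording_with_pulses([0.01, 0.02, 0.03])
        evs = extract_events(rec, detect_eods(rec, np.full(7, 0.1)))
        avg = average_waveform(evs)
        flags, scores = doublet_screen(evs, avg, flag_fraction=0.5)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)
        assert all(f.event_index != 0 or f.residual_score > 0 for f in flags)

    def test_planted_doublet_scores_highest(self):
        # 30 clean jittered events + 1 superimposed pair 150 us apart
        times = list(0.0015 + 0.0006 * np.arange(30))
        rec = recording_with_pulses(times, noise=0.005, seed=8,
                                    duration=0.03)
        t_doublet = 0.025
        extra = recording_with_pulses([t_doublet, t_doublet + 150e-6],
                                      duration=0.03)
        rec = MultichannelRecording(rec.samples + extra.samples, FS)
        evs = extract_events(rec, detect_eods(rec, np.full(7, 0.1)))
        avg = average_waveform(evs)
        _, scores = doublet_screen(evs, avg)
        assert np.argmax(scores) == len(evs) - 1  # the doublet is last

    def test_flag_count_quantile_arithmetic(self):
        rng = np.random.default_rng(9)
        rec = recording_with_pulses([0.01])
        base = align_and_extract(rec, int(0.01 * FS))
        events = []
        for _ in range(1000):
            w = base.window + rng.normal(0, 0.02, base.window.shape)
            events.append(EodEvent(base.peak_index, w, 34, 16))
        avg = average_waveform(events)
        flags, _ = doublet_screen(events, avg, flag_fraction=0.01)
        assert len(flags) == 10
        assert all(f1.residual_score >= f2.residual_score
                   for f1, f2 in zip(flags, flags[1:]))


class TestCaptureCurve:
    def test_curve_monotone_and_exhaustive(self, tmp_path):
        from pulseid.eod import doublet_capture_curve, plot_doublet_capture
        rng = np.random.default_rng(12)
        scores = np.concatenate([rng.uniform(0, 1, 97),
                                 rng.uniform(5, 6, 3)])
        labels = np.concatenate([np.zeros(97, bool), np.ones(3, bool)])
        curve = doublet_capture_curve(scores, labels)
        assert np.all(np.diff(curve["frac_doublets_found"]) >= 0)
        assert curve["frac_doublets_found"].iloc[-1] == pytest.approx(1.0)
        # the three planted doublets head the inspection order
        assert curve["frac_doublets_found"].iloc[2] == pytest.approx(1.0)
        out = tmp_path / "capture.png"
        plot_doublet_capture(curve, out)
        assert out.exists()


class TestConfirmDoublets:
    def make_flags(self, n=3):
        rec = recording_with_pulses([0.01])
        ev = align_and_extract(rec, int(0.01 * FS))
        return [DoubletFlag(i, ev, 1.0 + i, 0.5) for i in range(n)]

    def test_all_clean_empty_output(self):
        flags = self.make_flags()
        out = confirm_doublets(flags, {0: False, 1: False, 2: False})
        assert len(out) == 0
        assert all(f.confirmed == "clean" for f in flags)

    def test_all_doublet_full_output(self):
        flags = self.make_flags()
        out = confirm_doublets(flags, {0: True, 1: True, 2: True})
        assert len(out) == len(flags)

    def test_unresolved_flags_rejected(self):
        flags = self.make_flags()
        with pytest.raises(PendingReviewError):
            confirm_doublets(flags, {0: True})

    def test_decisions_round_trip_csv(self, tmp_path):
        import pandas as pd
        flags = self.make_flags()
        path = tmp_path / "decisions.csv"
        pd.DataFrame({"event_id": [0, 1, 2],
                      "doublet": [True, False, True]}).to_csv(path,
                                                              index=False)
        out = confirm_doublets(flags, path)
        assert len(out) == 2


class TestRecordingIO:
    def test_wav_round_trip(self, tmp_path):
        rec = recording_with_pulses([0.01], noise=0.01, seed=10)
        path = tmp_path / "rec.wav"
        rec.to_wav(path)
        back = MultichannelRecording.from_wav(path)
        assert back.sampling_rate == rec.sampling_rate
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)

    def test_raw_round_trip(self, tmp_path):
        rec = recording_with_pulses([0.01], noise=0.01, seed=11)
        path = tmp_path / "rec.f32"
        rec.to_raw(path)
        back = MultichannelRecording.from_raw(path)
        assert back.n_channels == 7
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)
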