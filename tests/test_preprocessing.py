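import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import eegident as ei
from eegident.preprocessing import butter_sos


def rec(samples, fs=160.0, label=1):
    samples = np.asarray(samples, dtype=float)
    labels = tuple(f"C{i}" for i in range(samples.shape[0]))
    return ei.EEGRecording(samples, fs, labels, label)


class TestCAR:
    def test_hand_example_two_channels(self):
        out = ei.car_filter(rec([[1, 2, 3], [3, 4, 5]]))
        np.testing.assert_allclose(out.samples, [[-1, -1, -1], [1, 1, 1]])

    def test_identical_channels_cancel(self):
        out = ei.car_filter(rec(np.ones((4, 100))))
        np.testing.assert_allclose(out.samples, 0.0)

    def test_column_sums_zero_and_idempotent(self):
        rng = np.random.default_rng(0)
        r = rec(rng.standard_normal((5, 200)))
        once = ei.car_filter(r)
        np.testing.assert_allclose(once.samples.sum(axis=0), 0.0, atol=1e-12)
        twice = ei.car_filter(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            ei.car_filter(rec(np.ones((1, 10))))


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = ei.bandpass(rec(np.zeros((2, 500))), 2, (8, 13))
        np.testing.assert_allclose(out.samples, 0.0)

    def test_passband_center_tone_preserved(self):
        # oracle: the design's own frequency response at the tone frequency
        fs, f0 = 160.0, np.sqrt(8 * 13.0)
        t = np.arange(int(20 * fs)) / fs
        tone = np.sin(2 * np.pi * f0 * t)
        out = ei.bandpass(rec([tone, tone]), 2, (8, 13), "zero_phase")
        trimmed = out.samples[0][800:-800]
        measured = np.sqrt(2) * trimmed.std()
        _, h = signal.sosfreqz(butter_sos(2, (8, 13), fs), worN=[f0], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward-backward applies |H|^2
        assert abs(measured - expected) / expected < 0.05
        assert abs(measured - 1.0) < 0.05

    def test_stopband_tone_rejected(self):
        fs = 160.0
        t = np.arange(int(20 * fs)) / fs
        tone = np.sin(2 * np.pi * 26.0 * t)  # 2x the upper edge of (8, 13)
        out = ei.bandpass(rec([tone, tone]), 5, (8, 13), "causal")
        in_rms = np.sqrt(np.mean(tone**2))
        out_rms = np.sqrt(np.mean(out.samples[0][800:] ** 2))
        assert out_rms < 0.10 * in_rms

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ei.bandpass(rec(np.zeros((2, 100))), 2, (50, 30))

    def test_commutes_with_car(self):
        rng = np.random.default_rng(1)
        r = rec(rng.standard_normal((4, 1000)))
        a = ei.bandpass(ei.car_filter(r), 3, (8, 13), "causal")
        b = ei.car_filter(ei.bandpass(r, 3, (8, 13), "causal"))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-10)


class TestSegmentation:
    def test_reference_segmentation_gives_19_windows(self):
        r = rec(np.zeros((2, 9600)))  # 60 s at 160 Hz
        segs = ei.segment(r, 5.0, 0.4)
        assert segs.n_segments == 19
        assert segs.segments.shape == (19, 2, 800)

    def test_ten_second_recording_gives_two_windows(self):
        r = rec(np.arange(2 * 1600).reshape(2, 1600))  # 10 s
        segs = ei.segment(r, 5.0, 0.4)
        assert segs.n_segments == 2
        # starts at 0 s and 3 s
        np.testing.assert_array_equal(segs.segments[0], r.samples[:, :800])
        np.testing.assert_array_equal(segs.segments[1], r.samples[:, 480:1280])

    @pytest.mark.parametrize("overlap", [0.0, 0.4, 0.9])
    def test_window_equal_to_duration_gives_one_segment(self, overlap):
        r = rec(np.zeros((2, 800)))  # V = v = 5 s
        assert ei.segment(r, 5.0, overlap).n_segments == 1

    def test_non_integer_hop_rejected_with_guidance(self):
        r = rec(np.zeros((2, 1600)))
        with pytest.raises(ValueError, match="hop"):
            ei.segment(r, 5.0, 0.3333)

    @settings(max_examples=200, deadline=None)
    @given(
        n_windows=st.integers(1, 30),
        win=st.integers(2, 50),
        hop=st.integers(1, 50),
        extra=st.integers(0, 49),
    )
    def test_count_formula_matches_window_enumeration(self, n_windows, win, hop, extra):
        """The closed-form N agrees with explicitly enumerated window starts
        for arbitrary (duration, window, hop) sample grids."""
        hop = min(hop, win)  # overlap >= 0
        n_samples = win + (n_windows - 1) * hop + min(extra, hop - 1)
        fs = 1.0
        starts = [s for s in range(0, n_samples - win + 1, hop)]
        duration, seg_len, alpha = n_samples / fs, win / fs, 1.0 - hop / win
        assert ei.segment_count(duration, seg_len, alpha) == len(starts) == n_windows
        r = rec(np.zeros((2, n_samples)), fs=fs)
        assert ei.segment(r, seg_len, alpha).n_segments == n_windows
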