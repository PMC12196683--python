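"""Filtering, segmentation and MAV normalization."""

import numpy as np
import pytest

from emgfusion.preprocess import (FilterSpec, SegmentSet, bandpass_gain,
                                  design_bandpass, extract_segments,
                                  filter_recording, mav_normalize,
                                  segments_from_recordings)
from emgfusion.synth import Recording
from emgfusion.gestures import Gesture


def _butter_magnitude(spec, f):
    """Closed-form digital Butterworth bandpass magnitude (bilinear prewarp)."""
    v = np.tan(np.pi * f / spec.sampling_rate)
    v1 = np.tan(np.pi * spec.low_cut / spec.sampling_rate)
    v2 = np.tan(np.pi * spec.high_cut / spec.sampling_rate)
    W = (v * v - v1 * v2) / (v * (v2 - v1))
    return 1.0 / np.sqrt(1.0 + W ** (2 * spec.order))


def _recording(signal):
    return Recording("S001", "single", "paretic", Gesture.FIST, 0,
                     signal.astype(np.float32))


class TestDesignBandpass:
    def test_gain_matches_analytic_formula(self):
        spec = FilterSpec()
        for f in (5.0, 20.0, 77.5, 150.0, 300.0, 450.0):
            assert bandpass_gain(spec, f) == pytest.approx(
                _butter_magnitude(spec, f), abs=1e-9)

    def test_midband_near_unity_stopbands_rejected(self):
        spec = FilterSpec()
        assert bandpass_gain(spec, 77.5) >= 0.99
        assert bandpass_gain(spec, 5.0) < 0.1
        assert bandpass_gain(spec, 450.0) < 0.1

    @pytest.mark.parametrize("kwargs", [
        {"order": 0}, {"low_cut": 0.0}, {"low_cut": 300.0, "high_cut": 20.0},
        {"high_cut": 600.0}])
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            FilterSpec(**kwargs)

    def test_sos_shape(self):
        sos = design_bandpass(FilterSpec())
        assert sos.shape[1] == 6


class TestFilterRecording:
    def test_dc_is_rejected(self):
        rec = _recording(np.full((750, 4), 0.7))
        out = filter_recording(rec, FilterSpec())
        assert np.abs(out.signal).max() < 1e-6 * 0.7

    def test_passband_sine_preserved(self):
        t = np.arange(750) / 1000
        sig = np.sin(2 * np.pi * 100 * t)[:, None].repeat(4, axis=1)
        out = filter_recording(_recording(sig), FilterSpec()).signal[100:-100]
        rms_in = np.sqrt(np.mean(sig[100:-100] ** 2))
        rms_out = np.sqrt(np.mean(out ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_idempotent_on_passband_content(self, rng):
        noise = rng.standard_normal((750, 4)).astype(np.float32)
        once = filter_recording(_recording(noise), FilterSpec())
        twice = filter_recording(once, FilterSpec())
        # a second pass only reshapes transition-band leakage; deep inside
        # the passband (40-250 Hz) it is a no-op
        freqs = np.fft.rfftfreq(750, d=1e-3)
        band = (freqs >= 40) & (freqs <= 250)
        spec_diff = np.abs(np.fft.rfft(twice.signal - once.signal, axis=0))[band]
        spec_ref = np.abs(np.fft.rfft(once.signal, axis=0))[band]
        assert np.sqrt((spec_diff ** 2).sum()) < 0.02 * np.sqrt((spec_ref ** 2).sum())

    def test_sampling_rate_mismatch(self):
        with pytest.raises(ValueError, match="Hz"):
            filter_recording(_recording(np.zeros((750, 4))),
                             FilterSpec(sampling_rate=2000))

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="short"):
            filter_recording(_recording(np.zeros((10, 4))), FilterSpec())

    def test_per_channel_operation_commutes_with_permutation(self, rng):
        sig = rng.standard_normal((750, 4)).astype(np.float32)
        perm = [2, 0, 3, 1]
        a = filter_recording(_recording(sig[:, perm]), FilterSpec()).signal
        b = filter_recording(_recording(sig), FilterSpec()).signal[:, perm]
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestExtractSegments:
    def test_windows_and_labels(self, rng):
        stream = rng.standard_normal((3000, 4)).astype(np.float32)
        markers = [0, 800, 1700]
        labels = ["rest", "fist", "rest"]
        segs = extract_segments(stream, markers, labels, subject_id="S1")
        assert len(segs) == 3
        assert segs.X.shape == (3, 750, 4)
        assert list(segs.gestures) == labels
        np.testing.assert_array_equal(segs.X[1], stream[800:1550])

    def test_empty_markers(self):
        segs = extract_segments(np.zeros((100, 4)), [], [])
        assert len(segs) == 0

    def test_overrun_names_the_marker(self):
        with pytest.raises(ValueError, match="marker 1"):
            extract_segments(np.zeros((1000, 4)), [0, 500], ["rest", "rest"])


class TestMavNormalize:
    def _segset(self, X, subjects=None, arms=None):
        import pandas as pd
        n = X.shape[0]
        meta = pd.DataFrame({
            "subject_id": subjects or ["S1"] * n,
            "session": ["single"] * n,
            "arm": arms or ["paretic"] * n,
            "gesture": ["fist"] * n,
            "repetition": range(n)})
        return SegmentSet(X.astype(np.float32), meta)

    def test_group_mav_is_unity_after_normalization(self, rng):
        X = rng.standard_normal((6, 750, 4))
        out = mav_normalize(self._segset(X))
        assert np.mean(np.abs(out.X), axis=(0, 1)) == pytest.approx(
            np.ones(4), abs=1e-5)

    def test_scale_invariance(self, rng):
        X = rng.standard_normal((4, 750, 4))
        a = mav_normalize(self._segset(X)).X
        b = mav_normalize(self._segset(10 * X)).X
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_groups_normalized_independently(self, rng):
        X = rng.standard_normal((4, 750, 4))
        X[2:] *= 7  # second subject much stronger
        out = mav_normalize(self._segset(X, subjects=["S1", "S1", "S2", "S2"]))
        for idx in ([0, 1], [2, 3]):
            assert np.mean(np.abs(out.X[idx]), axis=(0, 1)) == pytest.approx(
                np.ones(4), abs=1e-6)

    def test_zero_channel_guard(self):
        X = np.ones((2, 750, 4), dtype=np.float32)
        X[:, :, 2] = 0.0
        out = mav_normalize(self._segset(X))
        assert np.all(out.X[:, :, 2] == 0.0)
        guarded = out.norm_stats.query("channel == 2")["eps_guarded"]
        assert guarded.all()

    def test_per_segment_variant(self, rng):
        X = rng.standard_normal((3, 750, 4))
        out = mav_normalize(self._segset(X), per_segment=True)
        assert np.mean(np.abs(out.X), axis=1) == pytest.approx(
            np.ones((3, 4)), abs=1e-5)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            mav_normalize(self._segset(np.empty((0, 750, 4))))


def test_pipeline_preserves_counts_and_labels(small_recordings):
    segs = segments_from_recordings(small_recordings)
    normed = mav_normalize(segs)
    assert len(normed) == len(small_recordings)
    assert list(normed.gestures) == [r.gesture.value
                                     for r in small_recordings.recordings]


def test_segmentset_save_load_roundtrip(tmp_path, small_segments):
    sub = small_segments.subset(np.arange(4))
    sub.save(tmp_path)
    again = SegmentSet.load(tmp_path)
    assert len(again) == 4
    np.testing.assert_allclose(again.X, sub.X, atol=1e-5)
    assert list(again.gestures) == list(sub.gestures)
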