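"""Synthetic EMG generator: device realism, paresis effects, determinism."""

import numpy as np
import pytest

import emgfusion as ef
from emgfusion.gestures import Gesture, GESTURES
from emgfusion.preprocess import extract_segments
from emgfusion.synth import (SimConfig, SubjectProfile, concatenate_session,
                             make_default_templates, simulate_cohort,
                             simulate_repetition, draw_profile)


@pytest.fixture(scope="module")
def templates():
    return make_default_templates()


@pytest.fixture(scope="module")
def config():
    return SimConfig(seed=0)


def _mav(signal):
    return np.mean(np.abs(signal), axis=0)


class TestTemplates:
    def test_one_template_per_gesture(self, templates):
        assert set(templates) == set(GESTURES)
        assert len(templates) == 7

    def test_rest_is_noise_floor_only(self, templates):
        assert max(templates[Gesture.REST].channel_gains) == 0.0

    def test_wrist_extension_dominant_on_extensor_channel(self, templates):
        gains = templates[Gesture.WRIST_EXTENSION].channel_gains
        assert gains[3] > max(gains[:3])


class TestSimulateRepetition:
    def test_shape_and_device_clipping(self, templates, config):
        prof = draw_profile("S001", config, np.random.default_rng(1))
        for g in GESTURES:
            rec = simulate_repetition(templates[g], prof, "paretic", config,
                                      np.random.default_rng(2))
            assert rec.signal.shape == (750, 4)
            assert np.abs(rec.signal).max() <= config.device_limit

    def test_identity_profile_makes_arms_identical(self, templates, config):
        prof = SubjectProfile("S001")     # alpha=1, no leakage, no tremor
        a = simulate_repetition(templates[Gesture.FIST], prof, "paretic",
                                config, np.random.default_rng(7))
        b = simulate_repetition(templates[Gesture.FIST], prof, "non_paretic",
                                config, np.random.default_rng(7))
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_attenuation_reduces_active_channel_amplitude(self, templates, config):
        """Monte-Carlo: alpha=0.6 paretic MAV < non-paretic MAV on active channels."""
        prof = SubjectProfile("S001", alpha=0.6)
        par, non = [], []
        for i in range(200):
            par.append(_mav(simulate_repetition(
                templates[Gesture.FIST], prof, "paretic", config,
                np.random.default_rng(100 + i)).signal)[:3].mean())
            non.append(_mav(simulate_repetition(
                templates[Gesture.FIST], prof, "non_paretic", config,
                np.random.default_rng(100 + i)).signal)[:3].mean())
        assert np.mean(par) < np.mean(non)

    def test_attenuation_is_monotone_in_alpha(self, templates, config):
        means = []
        for alpha in (0.3, 0.6, 0.9):
            prof = SubjectProfile("S001", alpha=alpha)
            mavs = [_mav(simulate_repetition(templates[Gesture.FIST], prof,
                                             "paretic", config,
                                             np.random.default_rng(200 + i)
                                             ).signal)[:3].mean()
                    for i in range(50)]
            means.append(np.mean(mavs))
        assert means[0] < means[1] < means[2]

    def test_cocontraction_leaks_flexion_into_extensor_channel(self, templates, config):
        low = SubjectProfile("S001", cocontraction=0.0)
        high = SubjectProfile("S001", cocontraction=0.5)
        leak = {}
        for name, prof in (("low", low), ("high", high)):
            vals = [_mav(simulate_repetition(templates[Gesture.WRIST_FLEXION],
                                             prof, "paretic", config,
                                             np.random.default_rng(300 + i)
                                             ).signal)[3]
                    for i in range(50)]
            leak[name] = np.mean(vals)
        assert leak["high"] > leak["low"]

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1.5}, {"cocontraction": 1.0},
        {"tremor_depth": 1.0}, {"noise_floor_multiplier": 0.5}])
    def test_invalid_profile_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SubjectProfile("S001", **kwargs)

    def test_unknown_arm(self, templates, config):
        with pytest.raises(ValueError, match="arm"):
            simulate_repetition(templates[Gesture.REST], SubjectProfile("S"),
                                "left", config, np.random.default_rng(0))


class TestSimulateCohort:
    def test_balanced_counts(self, small_recordings):
        # 4 subjects x 2 arms x 7 gestures x 3 reps
        assert len(small_recordings) == 4 * 2 * 7 * 3
        counts = small_recordings.manifest().groupby(
            ["subject_id", "arm", "gesture"]).size()
        assert (counts == 3).all()

    def test_same_seed_is_bit_identical(self, cohort):
        sub = ef.Cohort(cohort.records[:2])
        sim = ef.SimConfig(seed=9, reps_per_class=2, raw_reps_range=(2, 4))
        a = simulate_cohort(sub, sim)
        b = simulate_cohort(sub, sim)
        for ra, rb in zip(a.recordings, b.recordings):
            assert ra.key == rb.key
            np.testing.assert_array_equal(ra.signal, rb.signal)

    def test_severity_follows_motor_score(self, config):
        """A near-intact patient (FMA-UE 64) is less degraded than a severe one (8)."""
        rng = np.random.default_rng(0)
        mild = draw_profile("S003", config, np.random.default_rng(3), fma_ue=64)
        severe = draw_profile("S017", config, np.random.default_rng(3), fma_ue=8)
        assert mild.alpha > severe.alpha
        assert mild.cocontraction < severe.cocontraction
        assert mild.tremor_depth < severe.tremor_depth

    def test_class_centroids_distinct_without_paresis(self, cohort):
        """MAV feature centroids of the 7 classes are pairwise separated."""
        sub = ef.Cohort(cohort.records[:1])
        sim = SimConfig(seed=5, reps_per_class=10, raw_reps_range=(10, 10),
                        paresis_alpha=1.0, paresis_cocontraction=0.0,
                        paresis_tremor_depth=0.0, paresis_noise_mult=1.0)
        recs = simulate_cohort(sub, sim).select(arm="non_paretic")
        centroids = {}
        for g in GESTURES:
            sigs = [r.signal for r in recs.select(gesture=g).recordings]
            centroids[g] = np.mean([_mav(s) for s in sigs], axis=0)
        names = list(GESTURES)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = np.linalg.norm(centroids[names[i]] - centroids[names[j]])
                assert d > 0.05, (names[i], names[j])


class TestConcatenateSession:
    def test_roundtrip_recovers_segments(self, small_recordings):
        one = small_recordings.select(subject_id="S001", arm="paretic")
        stream, markers = concatenate_session(one.recordings,
                                              rng=np.random.default_rng(0))
        assert len(markers) == len(one.recordings)
        assert (np.diff(markers) > 0).all()
        n_gap = int(0.5 * 1000)
        assert stream.shape[0] == sum(r.signal.shape[0] for r in one.recordings) \
            + n_gap * len(one.recordings)
        segs = extract_segments(stream, markers,
                                [r.gesture for r in one.recordings],
                                subject_id="S001", arm="paretic")
        for i, r in enumerate(one.recordings):
            np.testing.assert_array_equal(segs.X[i], r.signal)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            concatenate_session([])

    def test_mixed_subjects_rejected(self, small_recordings):
        mixed = (small_recordings.select(subject_id="S001", arm="paretic").recordings[:1]
                 + small_recordings.select(subject_id="S002", arm="paretic").recordings[:1])
        with pytest.raises(ValueError, match="share"):
            concatenate_session(mixed)


def test_recordingset_save_load_roundtrip(tmp_path, small_recordings):
    subset = ef.synth.RecordingSet(small_recordings.recordings[:5])
    subset.save(tmp_path, fmt="%.6f")
    again = ef.synth.RecordingSet.load(tmp_path)
    assert len(again) == 5
    for a, b in zip(subset.recordings, again.recordings):
        assert a.key == b.key
        np.testing.assert_allclose(a.signal, b.signal, atol=1e-6)
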