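"""Tests of the synthetic recording generator."""

import dataclasses

import numpy as np
import pytest

from beatsource import SynthConfig, make_heart_rate_trace, make_recording, synth_beat_train
from beatsource.signals import FETAL, SILENT, VESSEL, ARTIFACT, HeartRateTrace

from conftest import constant_trace
from oracles import envelope_peak_count


class TestHeartRateTraces:
    def test_zero_variability_fetal_trace_is_flat(self):
        cfg = SynthConfig(duration_s=10.0, fetal_variability_bpm=0.0, seed=1)
        trace = make_heart_rate_trace("fetal", cfg)
        assert len(trace) == 40
        assert np.all(trace.values_bpm == 140.0)

    def test_maternal_drift_stays_within_amplitude_bound(self):
        cfg = SynthConfig(duration_s=60.0, maternal_baseline_bpm=80.0,
                          maternal_drift_bpm=8.0, seed=5)
        trace = make_heart_rate_trace("maternal", cfg)
        assert len(trace) == 240
        assert trace.values_bpm.min() >= 72.0
        assert trace.values_bpm.max() <= 88.0

    def test_fetal_variability_bounded_and_band_limited(self):
        cfg = SynthConfig(duration_s=120.0, fetal_variability_bpm=10.0, seed=9)
        trace = make_heart_rate_trace("fetal", cfg)
        dev = trace.values_bpm - 140.0
        assert np.max(np.abs(dev)) <= 10.0 + 1e-9
        assert np.max(np.abs(np.diff(dev))) < 3.0  # slow variation at 4 Hz

    def test_same_config_reproduces_identical_trace(self):
        cfg = SynthConfig(duration_s=30.0, seed=11)
        a = make_heart_rate_trace("fetal", cfg)
        b = make_heart_rate_trace("fetal", cfg)
        np.testing.assert_array_equal(a.values_bpm, b.values_bpm)

    def test_invalid_kind_and_duration_rejected(self):
        with pytest.raises(ValueError):
            make_heart_rate_trace("paternal", SynthConfig(duration_s=10.0))
        with pytest.raises(ValueError):
            make_heart_rate_trace("fetal", SynthConfig(duration_s=-1.0))


class TestBeatTrains:
    @pytest.mark.parametrize("source,expected", [("fetal", 4), ("vessel", 2)])
    def test_burst_count_at_120_bpm_one_second(self, source, expected):
        # 2 beats in 1 s: the fetal heart shows two bursts each, a vessel one
        cfg = SynthConfig(duration_s=1.0, timing_jitter_ms=0.0,
                          amplitude_jitter_cv=0.0, seed=2)
        sig = synth_beat_train(constant_trace(120.0, 1.0), source, cfg)
        assert envelope_peak_count(sig.samples) == expected

    def test_burst_counts_disjoint_across_seeds(self):
        for seed in range(12):
            cfg = SynthConfig(duration_s=1.0, seed=seed)
            f = envelope_peak_count(synth_beat_train(constant_trace(120.0, 1.0), "fetal", cfg).samples)
            v = envelope_peak_count(synth_beat_train(constant_trace(120.0, 1.0), "vessel", cfg).samples)
            assert f == 4 and v == 2

    def test_one_hertz_rate_gives_two_beats_in_two_seconds(self):
        cfg = SynthConfig(duration_s=2.0, timing_jitter_ms=0.0,
                          amplitude_jitter_cv=0.0, seed=4)
        for source, per_beat in (("fetal", 2), ("vessel", 1)):
            sig = synth_beat_train(constant_trace(60.0, 2.0), source, cfg)
            assert envelope_peak_count(sig.samples) == 2 * per_beat

    def test_peak_amplitude_below_one_and_rms_at_target(self):
        cfg = SynthConfig(duration_s=10.0, seed=6)
        sig = synth_beat_train(constant_trace(140.0, 10.0), "fetal", cfg)
        assert np.max(np.abs(sig.samples)) <= 1.0
        assert np.sqrt(np.mean(sig.samples**2)) == pytest.approx(cfg.target_rms, rel=0.05)

    def test_nonpositive_heart_rate_rejected(self):
        cfg = SynthConfig(duration_s=1.0, seed=0)
        bad = HeartRateTrace(np.array([140.0, -3.0, 140.0, 140.0]), kind="FHR")
        with pytest.raises(ValueError):
            synth_beat_train(bad, "fetal", cfg)


class TestRecordings:
    def test_crossing_episode_annotation_and_trace_switch(self):
        cfg = SynthConfig(duration_s=60.0, crossing_episodes=((30.0, 50.0),), seed=7)
        rec, ann = make_recording(cfg)
        codes = ann.codes
        assert np.all(codes[30_000:50_000] == VESSEL)
        assert np.all(codes[:30_000] == FETAL) and np.all(codes[50_000:] == FETAL)
        # displayed FHR equals MHR on trace samples 120..199
        np.testing.assert_array_equal(
            rec.fhr.values_bpm[120:200], rec.mhr.values_bpm[120:200]
        )
        assert np.any(rec.fhr.values_bpm[:120] != rec.mhr.values_bpm[:120])

    def test_noiseless_recording_equals_pure_fetal_train(self, quiet_cfg):
        rec, _ = make_recording(quiet_cfg)
        fhr = make_heart_rate_trace("fetal", quiet_cfg)
        train = synth_beat_train(fhr, "fetal", quiet_cfg)
        np.testing.assert_array_equal(rec.dus.samples, train.samples)

    def test_duration_arithmetic_consistency(self):
        cfg = SynthConfig(duration_s=600.0, seed=8)
        rec, ann = make_recording(cfg)
        assert len(rec.dus) == 600_000
        assert len(rec.fhr) == 2400 and len(rec.mhr) == 2400
        assert len(ann) == len(rec.dus)
        assert len(rec.dus) / 1000 == len(rec.fhr) / 4

    def test_bit_identical_reproduction_from_seed(self):
        cfg = SynthConfig(duration_s=40.0, crossing_episodes=((10.0, 20.0),), seed=13)
        a, _ = make_recording(cfg)
        b, _ = make_recording(cfg)
        np.testing.assert_array_equal(a.dus.samples, b.dus.samples)
        np.testing.assert_array_equal(a.fhr.values_bpm, b.fhr.values_bpm)

    def test_dropout_and_artifact_episodes(self):
        cfg = SynthConfig(duration_s=40.0, dropout_episodes=((10.0, 15.0),),
                          artifact_episodes=((25.0, 30.0),), snr_db=None, seed=3)
        rec, ann = make_recording(cfg)
        assert np.all(ann.codes[10_000:15_000] == SILENT)
        assert np.all(ann.codes[25_000:30_000] == ARTIFACT)
        quiet = np.abs(rec.dus.samples[10_000:15_000]).max()
        loud = rec.dus.samples[25_000:30_000].std()
        assert quiet <= 0.01 * np.abs(rec.dus.samples).max()
        assert loud > 2 * rec.dus.samples[:10_000].std()

    def test_overlapping_cross_category_episodes_rejected(self):
        cfg = SynthConfig(duration_s=40.0, crossing_episodes=((10.0, 20.0),),
                          dropout_episodes=((15.0, 25.0),), seed=0)
        with pytest.raises(ValueError, match="overlap"):
            make_recording(cfg)

    def test_coincidence_episode_pulls_mhr_within_five_bpm(self):
        cfg = SynthConfig(duration_s=60.0, coincidence_episodes=((20.0, 40.0),), seed=21)
        rec, ann = make_recording(cfg)
        inside = slice(80, 160)
        assert np.all(np.abs(rec.fhr.values_bpm[inside] - rec.mhr.values_bpm[inside]) < 5.0)
        assert np.all(ann.codes == FETAL)  # source never switches

    def test_morphology_separability_over_many_windows(self):
        """Envelope peak-per-beat ratios of fetal and vessel 2-s windows are
        disjoint (2 vs 1 per beat) across >= 100 windows per class."""
        ratios = {"fetal": [], "vessel": []}
        for seed in range(4):
            cfg = SynthConfig(duration_s=60.0, seed=seed)
            for source, rate in (("fetal", 140.0), ("vessel", 80.0)):
                sig = synth_beat_train(constant_trace(rate, 60.0), source, cfg)
                for k in range(29):
                    w = sig.samples[k * 2000: k * 2000 + 2000]
                    beats = rate / 60.0 * 2.0
                    ratios[source].append(envelope_peak_count(w) / beats)
        assert len(ratios["fetal"]) >= 100 and len(ratios["vessel"]) >= 100
        assert min(ratios["fetal"]) > max(ratios["vessel"])
        assert np.median(ratios["fetal"]) == pytest.approx(2.0, abs=0.35)
        assert np.median(ratios["vessel"]) == pytest.approx(1.0, abs=0.35)


class TestConfigValidation:
    def test_carrier_must_stay_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SynthConfig(burst_carrier_hz=600.0).validate()

    def test_bpm_range_enforced(self):
        with pytest.raises(ValueError):
            SynthConfig(maternal_baseline_bpm=45.0).validate()

    def test_episodes_must_lie_inside_recording(self):
        with pytest.raises(ValueError):
            SynthConfig(duration_s=30.0, crossing_episodes=((20.0, 40.0),)).validate()

    def test_overlapping_same_category_episodes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SynthConfig(duration_s=60.0,
                        crossing_episodes=((10.0, 30.0), (20.0, 40.0))).validate()
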