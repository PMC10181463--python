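"""Synthetic EEG generator: protocol structure, determinism, and the
closed-form class-statistics oracle."""

import json

import numpy as np
import pytest
import scipy.signal
import scipy.stats

from eegcascade.io_recordings import detect_trigger_pulses, read_recording, segment_tasks
from eegcascade.preprocess import trim_epoch, window_epoch
from eegcascade.synthetic import (
    SimulationConfig,
    class_statistics_oracle,
    generate_dataset,
    simulate_recording,
)

SMALL = dict(n_subjects=2, n_recordings=2)


class TestRecordingStructure:
    def test_default_session_duration_and_pulses(self, default_recording):
        assert default_recording.duration_s >= 240.0
        assert default_recording.fs == 512.0
        pulses = detect_trigger_pulses(default_recording.trigger, 512.0)
        assert len(pulses) == 9
        assert all(p.width == 256 for p in pulses)

    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        r1 = simulate_recording(cfg, 1, 0)
        r2 = simulate_recording(cfg, 1, 0)
        np.testing.assert_array_equal(r1.signals, r2.signals)
        np.testing.assert_array_equal(r1.trigger, r2.trigger)

    def test_different_subjects_differ(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        r1 = simulate_recording(cfg, 0, 0)
        r2 = simulate_recording(cfg, 1, 0)
        assert not np.allclose(r1.signals, r2.signals)

    def test_zeroed_config_yields_silence_plus_trigger(self):
        cfg = SimulationConfig(
            seed=0, n_subjects=1, n_recordings=1,
            background_sigma=0.0, skew_amp_right=0.0,
            kurt_amp_imagery=0.0, kurt_amp_real=0.0,
            line_amp=0.0, drift_amp=0.0, blink_rate=0.0, blink_amp=0.0,
        )
        rec = simulate_recording(cfg, 0, 0)
        np.testing.assert_array_equal(rec.signals, 0.0)
        assert rec.trigger.max() == cfg.trigger_amp

    def test_fp1_montage_has_single_channel(self):
        cfg = SimulationConfig(seed=0, montage="fp1", **SMALL)
        rec = simulate_recording(cfg, 0, 0)
        assert rec.channel_labels == ["FP1"]

    def test_out_of_range_subject_rejected(self):
        cfg = SimulationConfig(seed=0, **SMALL)
        with pytest.raises(ValueError, match="subject_index"):
            simulate_recording(cfg, 5, 0)


class TestClassStatisticsOracle:
    def test_zero_effects_make_classes_identical(self):
        cfg = SimulationConfig(seed=1, var_ratio_ankle=1.0, skew_amp_right=0.0,
                               kurt_amp_imagery=6.0, kurt_amp_real=6.0,
                               subject_sd=0.0, session_sd=0.0, **SMALL)
        stats = [class_statistics_oracle(cfg, 0, 0, lbl)
                 for lbl in cfg.protocol.tasks]
        for s in stats[1:]:
            for key in ("variance", "skewness", "excess_kurtosis"):
                np.testing.assert_allclose(s[key], stats[0][key])

    def test_variance_ratio_matches_construction(self):
        cfg = SimulationConfig(seed=1, var_ratio_ankle=2.0, subject_sd=0.0,
                               session_sd=0.0, line_amp=0.0, **SMALL)
        hand = class_statistics_oracle(cfg, 0, 0, "real-left-hand")
        ankle = class_statistics_oracle(cfg, 0, 0, "real-left-ankle")
        # blink-free channels scale exactly with the squared region gain
        assert ankle["variance"][2] / hand["variance"][2] \
            == pytest.approx(2.0, rel=1e-12)

    def test_estimated_moments_approach_oracle(self):
        # ~100 two-second windows per task against the closed forms; the
        # drift walk is excluded from the oracle, so it is disabled here
        cfg = SimulationConfig(seed=21, n_subjects=1, n_recordings=1,
                               drift_amp=0.0, blink_rate=0.0)
        rec = simulate_recording(cfg, 0, 0)
        pulses = detect_trigger_pulses(rec.trigger, rec.fs)
        epochs = segment_tasks(rec, pulses, cfg.protocol)
        for epoch in epochs[:4]:
            wins = window_epoch(epoch, 2.0, 0.75)
            ch = np.stack([w.signals[2] for w in wins])  # non-frontal channel
            oracle = class_statistics_oracle(cfg, 0, 0, epoch.label)
            # pool central moments over windows before forming the
            # standardized ratios (per-window ratios carry Jensen bias the
            # population quantities do not have)
            d = ch - ch.mean(axis=1, keepdims=True)
            m2 = (d ** 2).mean()
            m3 = (d ** 3).mean()
            m4 = (d ** 4).mean()
            assert m2 == pytest.approx(oracle["variance"][2], rel=0.10)
            assert m3 / m2 ** 1.5 == pytest.approx(oracle["skewness"][2],
                                                   abs=0.15)
            assert m4 / m2 ** 2 - 3 == pytest.approx(
                oracle["excess_kurtosis"][2], abs=0.25)

    def test_unknown_class_rejected(self):
        cfg = SimulationConfig(seed=0, **SMALL)
        with pytest.raises(ValueError):
            class_statistics_oracle(cfg, 0, 0, "jump-left-hand")


class TestNuisanceComponents:
    def test_blinks_confined_to_frontal_channels(self):
        quiet = SimulationConfig(seed=5, n_subjects=1, n_recordings=1,
                                 blink_rate=0.0)
        blinky = SimulationConfig(seed=5, n_subjects=1, n_recordings=1,
                                  blink_rate=1.0, blink_amp=200.0)
        r0 = simulate_recording(quiet, 0, 0)
        r1 = simulate_recording(blinky, 0, 0)
        labels = r1.channel_labels
        delta = np.abs(r1.signals - r0.signals).max(axis=1)
        for i, ch in enumerate(labels):
            if ch in ("Fp1", "Fp2"):
                assert delta[i] > 50.0
            else:
                assert delta[i] == pytest.approx(0.0, abs=1e-9)

    def test_line_component_concentrates_at_60hz(self):
        cfg = SimulationConfig(seed=3, n_subjects=1, n_recordings=1,
                               background_sigma=1.0, skew_amp_right=0.0,
                               kurt_amp_imagery=0.0, kurt_amp_real=0.0,
                               drift_amp=0.0, blink_rate=0.0, line_amp=30.0)
        rec = simulate_recording(cfg, 0, 0)
        f, psd = scipy.signal.welch(rec.signals[2], fs=rec.fs, nperseg=4096)
        band = lambda lo, hi: psd[(f >= lo) & (f <= hi)].sum()
        assert band(59.5, 60.5) / band(10.0, 11.0) > 10.0

    def test_bandpass_filter_attenuates_line_per_its_response(self):
        from eegcascade.preprocess import FilterSpec, bandpass_filter, frequency_response

        cfg = SimulationConfig(seed=3, n_subjects=1, n_recordings=1,
                               background_sigma=0.0, skew_amp_right=0.0,
                               kurt_amp_imagery=0.0, kurt_amp_real=0.0,
                               drift_amp=0.0, blink_rate=0.0, line_amp=10.0)
        rec = simulate_recording(cfg, 0, 0)
        filtered = bandpass_filter(rec.signals[0], rec.fs)
        (gain,) = frequency_response(FilterSpec(), rec.fs, [cfg.line_freq])
        mid = slice(10_000, 100_000)
        measured = filtered[mid].std() / rec.signals[0][mid].std()
        assert measured == pytest.approx(gain, rel=0.05)


class TestGenerateDataset:
    def test_default_small_dataset_files_and_manifest(self, tmp_path):
        cfg = SimulationConfig(seed=2, **SMALL)
        out = generate_dataset(cfg, tmp_path / "data")
        files = sorted(p.name for p in out.glob("*.csv"))
        assert len(files) == 4
        manifest = json.loads((out / "manifest.json").read_text())
        assert len(manifest["files"]) == 4
        assert manifest["seed"] == 2

    def test_fp1_dataset_recordings_have_one_channel(self, tmp_path):
        cfg = SimulationConfig(seed=2, montage="fp1", n_subjects=1,
                               n_recordings=1)
        out = generate_dataset(cfg, tmp_path / "data")
        rec = read_recording(out / "subject00_rec0.csv")
        assert rec.channel_labels == ["FP1"]

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_subjects=1, n_recordings=1)
        out1 = generate_dataset(cfg, tmp_path / "a")
        out2 = generate_dataset(cfg, tmp_path / "b")
        f1 = (out1 / "subject00_rec0.csv").read_bytes()
        f2 = (out2 / "subject00_rec0.csv").read_bytes()
        assert f1 == f2


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="montage"):
        SimulationConfig(montage="cap64")
    with pytest.raises(ValueError, match=">= 0"):
        SimulationConfig(blink_rate=-1.0)
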