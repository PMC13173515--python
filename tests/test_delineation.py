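"""Delineator accuracy against generator ground truth, plus edge cases."""

import numpy as np
import pytest

from rqtecg.core import ECGRecord, Morphology
from rqtecg.delineation import (
    DelineatorConfig,
    bandpass_filter,
    classify_t_morphology,
    delineate_record,
    detect_q_point,
    detect_r_peaks,
    detect_t_wave,
)
from rqtecg.synth import SyntheticSpec, generate_ecg

from conftest import FIVE_CLASSES, class_spec


def _rms(x):
    return float(np.sqrt(np.mean(x**2)))


class TestBandpass:
    def test_all_zero_signal_stays_zero(self):
        rec = ECGRecord(np.zeros(5000), fs=500)
        assert np.allclose(bandpass_filter(rec).samples, 0.0)

    def test_below_band_tone_attenuated(self):
        t = np.arange(30000) / 500.0
        rec = ECGRecord(np.sin(2 * np.pi * 0.1 * t), fs=500)
        out = bandpass_filter(rec, 0.5, 40.0)
        assert _rms(out.samples) < 0.1 * _rms(rec.samples)

    def test_in_band_tone_preserved(self):
        t = np.arange(30000) / 500.0
        rec = ECGRecord(np.sin(2 * np.pi * 10.0 * t), fs=500)
        out = bandpass_filter(rec, 0.5, 40.0)
        assert abs(_rms(out.samples) - _rms(rec.samples)) < 0.1 * _rms(rec.samples)

    def test_too_short_record_rejected(self):
        rec = ECGRecord(np.zeros(100), fs=500)
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(rec)


class TestRPeaks:
    def test_clean_record_all_beats_within_10_ms(self, clean_monophasic):
        record, truth = clean_monophasic
        det = detect_r_peaks(bandpass_filter(record))
        assert len(det) == len(truth)
        err_ms = np.abs(det - truth.r_peaks) * 1000.0 / record.fs
        assert np.max(err_ms) <= 10.0

    def test_all_zero_signal_yields_empty_result(self):
        rec = ECGRecord(np.zeros(10000), fs=500)
        assert detect_r_peaks(rec).size == 0

    def test_inverted_polarity_still_detected(self, clean_monophasic):
        record, truth = clean_monophasic
        neg = ECGRecord(-record.samples, fs=record.fs)
        det = detect_r_peaks(bandpass_filter(neg))
        assert len(det) == len(truth)
        err_ms = np.abs(det - truth.r_peaks) * 1000.0 / record.fs
        assert np.max(err_ms) <= 10.0


class TestQPoint:
    def test_clean_beats_within_10_ms_of_truth(self, delineated_monophasic):
        record, truth, det = delineated_monophasic
        err = (det.column("q_on") - truth.column("q_on")) * 1000.0 / record.fs
        assert np.nanmedian(np.abs(err)) <= 10.0

    def test_window_before_record_start_skips_beat(self):
        rec = ECGRecord(np.random.default_rng(0).normal(size=1000), fs=500)
        assert detect_q_point(rec, r_idx=10, q_window=150.0) is None

    def test_triangular_qrs_without_q_dip_returns_upstroke_onset(self):
        # symmetric triangle rising over 40 ms: onset is where the ramp starts
        fs = 500.0
        x = np.zeros(600)
        up = np.linspace(0, 1, 21)
        x[280:301] = up
        x[300:321] = up[::-1]
        rec = ECGRecord(x, fs=fs)
        q = detect_q_point(rec, r_idx=300, q_window=150.0)
        assert abs(q - 280) * 1000.0 / fs <= 10.0


class TestTWave:
    def test_flat_window_reports_absent_t(self):
        x = np.zeros(2000)
        x[500] = 1.0  # lone R spike, baseline elsewhere
        rec = ECGRecord(x, fs=500)
        t_peak, t_off, morph = detect_t_wave(rec, 500, rri_local=1000.0)
        assert t_peak is None and t_off is None
        assert morph is Morphology.FLAT

    def test_tangent_method_within_25_ms_on_clean_monophasic(self, clean_monophasic):
        record, truth = clean_monophasic
        cfg = DelineatorConfig(t_offset_method="tangent")
        det = delineate_record(record, cfg)
        err = (det.column("t_off") - truth.column("t_off")) * 1000.0 / record.fs
        assert np.nanmedian(np.abs(err)) <= 25.0

    def test_methods_agree_within_30_ms_on_clean_monophasic(self, clean_monophasic):
        record, truth = clean_monophasic
        offsets = {}
        for method in ("baseline_threshold", "tangent", "second_derivative"):
            det = delineate_record(record, DelineatorConfig(t_offset_method=method))
            offsets[method] = np.nanmedian(det.column("t_off") - truth.column("t_off"))
        spread = (max(offsets.values()) - min(offsets.values())) * 1000.0 / record.fs
        assert spread <= 30.0

    def test_window_shrinks_at_fast_rates(self, clean_monophasic):
        record, _ = clean_monophasic
        cfg = DelineatorConfig()
        r = 5000
        t_peak_fast, _, _ = detect_t_wave(record, r, rri_local=400.0, config=cfg)
        # at RR=400 ms the window caps at 280 ms, before this template's T peak
        t_peak_slow, _, _ = detect_t_wave(record, r, rri_local=1000.0, config=cfg)
        assert t_peak_slow is not None
        assert t_peak_fast is None or t_peak_fast < t_peak_slow


class TestMorphologyClassification:
    @pytest.mark.parametrize("morph", FIVE_CLASSES + [Morphology.MONOPHASIC_NEG])
    def test_generator_class_recovered(self, morph):
        record, truth = generate_ecg(class_spec(morph, n_beats=30))
        det = delineate_record(record)
        assert len(det) == 30
        acc = np.mean([a == b for a, b in zip(det.morphologies, truth.morphologies)])
        assert acc == 1.0

    def test_flat_threshold_boundary(self):
        seg = np.zeros(150)
        seg[60:90] = 0.05 * np.hanning(30)
        assert classify_t_morphology(seg, r_amp=1.0) is Morphology.FLAT

    def test_scale_invariance_of_labels(self, clean_monophasic):
        record, _ = clean_monophasic
        det1 = delineate_record(record)
        scaled = ECGRecord(record.samples * 7.3, fs=record.fs)
        det2 = delineate_record(scaled)
        assert det1.morphologies == det2.morphologies

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            classify_t_morphology(np.array([]), r_amp=1.0)


class TestDelineateRecord:
    def test_determinism(self, clean_monophasic):
        record, _ = clean_monophasic
        assert delineate_record(record).equals(delineate_record(record))

    def test_pure_noise_yields_empty_or_sparse_set(self):
        rng = np.random.default_rng(4)
        rec = ECGRecord(rng.normal(0, 0.01, 30000), fs=500)
        det = delineate_record(rec)
        assert len(det) <= 3  # no true beats to find

    def test_noisy_record_keeps_99_percent_of_beats(self):
        record, truth = generate_ecg(class_spec(Morphology.MONOPHASIC_POS, noise_sd=0.05))
        det = delineate_record(record)
        assert len(det) >= 0.99 * len(truth)
        q_err = (det.column("q_on")[: len(truth)] - truth.column("q_on")[: len(det)])
        assert np.nanmedian(np.abs(q_err)) * 1000.0 / record.fs <= 12.0
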