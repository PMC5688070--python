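import numpy as np
import pytest
from scipy import signal as sg

from scg_beatkit import (SimConfig, generate_recording, bandpass_scg,
                         detect_q, detect_r_peaks, detect_te, segment_beats)
from scg_beatkit.config import ConfigurationError, QConfig, TeConfig
from scg_beatkit.record_io import AnnotationStream, Record
from conftest import gauss_signal, make_beat

FS = 200.0


class TestBandpass:
    def test_dc_is_removed(self):
        x = np.full(2000, 7.5)
        y = bandpass_scg(x, FS)
        assert np.max(np.abs(y[200:-200])) < 1e-6 * 7.5

    def test_midband_gain_matches_designed_squared_response(self):
        # forward-reverse filtering applies |H(f)|^2 with zero phase; compare
        # the steady-state amplitude of a 20 Hz tone with the analytic gain
        t = np.arange(0, 10.0, 1 / FS)
        x = np.sin(2 * np.pi * 20.0 * t)
        y = bandpass_scg(x, FS)
        sos = sg.butter(2, [5.0, 40.0], btype="bandpass", fs=FS, output="sos")
        w, h = sg.sosfreqz(sos, worN=4096, fs=FS)
        expect = np.interp(20.0, w, np.abs(h)) ** 2
        mid = slice(400, 1800)                     # integer number of periods
        amp = np.sqrt(2.0) * np.sqrt(np.mean(y[mid] ** 2))
        assert amp == pytest.approx(expect, rel=0.01)
        # zero phase: demodulated phase shift corresponds to < 0.1 ms lag
        carrier = np.exp(-2j * np.pi * 20.0 * t[mid])
        dphi = np.angle(np.sum(y[mid] * carrier) / np.sum(x[mid] * carrier))
        assert abs(dphi) / (2 * np.pi * 20.0) * 1000.0 < 0.1

    def test_time_reversal_symmetry(self):
        # a burst embedded in zero padding, so both ends present the filter
        # with identical (zero) edge conditions
        rng = np.random.default_rng(3)
        x = np.zeros(800)
        x[300:500] = sg.sosfiltfilt(
            sg.butter(4, [5, 40], btype="bandpass", fs=FS, output="sos"),
            rng.standard_normal(200)) * sg.windows.hann(200)
        np.testing.assert_allclose(bandpass_scg(x[::-1], FS),
                                   bandpass_scg(x, FS)[::-1],
                                   rtol=1e-7, atol=1e-9)

    def test_idempotent_on_midband_content(self):
        rng = np.random.default_rng(4)
        x = sg.sosfiltfilt(sg.butter(6, [15, 25], btype="bandpass", fs=FS,
                                     output="sos"), rng.standard_normal(4000))
        once = bandpass_scg(x, FS)
        twice = bandpass_scg(once, FS)
        mid = slice(500, -500)
        change = np.sqrt(np.mean((twice[mid] - once[mid]) ** 2))
        assert change < 0.01 * np.sqrt(np.mean(once[mid] ** 2))

    def test_nyquist_guard(self):
        with pytest.raises(ConfigurationError):
            bandpass_scg(np.zeros(1000), fs=75.0, high=40.0)


class TestSegmentation:
    def test_windows_and_rri_from_minus_200_offset(self):
        rec = Record(ecg=np.zeros(1000), scg=np.zeros(1000), fs=FS)
        ann = AnnotationStream(r_ms=np.array([1000.0, 1800.0, 2600.0]))
        beats = segment_beats(rec, ann, edge_guard_s=0.0)
        assert len(beats) == 2
        assert beats[0].start_time == 800.0 and beats[0].end_time == 1600.0
        assert beats[1].start_time == 1600.0 and beats[1].end_time == 2400.0
        assert all(b.rri == 800.0 for b in beats)

    def test_single_r_peak_yields_no_beats(self, caplog):
        rec = Record(ecg=np.zeros(1000), scg=np.zeros(1000), fs=FS)
        ann = AnnotationStream(r_ms=np.array([1000.0]))
        with caplog.at_level("WARNING"):
            assert segment_beats(rec, ann) == []

    def test_sample_counts_match_rri_for_grid_aligned_peaks(self):
        rng = np.random.default_rng(5)
        gaps = rng.integers(120, 240, size=100) * 5.0      # on the 5 ms grid
        r = 1000.0 + np.concatenate([[0.0], np.cumsum(gaps)])
        n = int((r[-1] + 1000) / 5)
        rec = Record(ecg=np.zeros(n), scg=np.zeros(n), fs=FS)
        beats = segment_beats(rec, AnnotationStream(r_ms=r), edge_guard_s=0.5)
        assert len(beats) == 100
        for b in beats:
            assert b.end_idx - b.start_idx == round(b.rri * FS / 1000.0)

    def test_windows_are_contiguous(self):
        rng = np.random.default_rng(6)
        r = 1000.0 + np.cumsum(rng.uniform(600, 1200, size=30))
        n = int((r[-1] + 1000) / 5)
        rec = Record(ecg=np.zeros(n), scg=np.zeros(n), fs=FS)
        beats = segment_beats(rec, AnnotationStream(r_ms=r))
        for a, b in zip(beats, beats[1:]):
            assert a.end_idx == b.start_idx

    def test_excluded_r_peaks_do_not_seed_beats(self):
        rec = Record(ecg=np.zeros(1000), scg=np.zeros(1000), fs=FS)
        ann = AnnotationStream(r_ms=np.array([1000.0, 1800.0, 2600.0]),
                               validity=np.array([True, False, True]))
        beats = segment_beats(rec, ann, edge_guard_s=0.0)
        assert len(beats) == 1 and beats[0].rri == 1600.0


class TestRPeaks:
    def test_count_and_accuracy_on_synthetic_ecg(self):
        cfg = SimConfig(duration_s=60.0, hr_profile=((0.0, 60.0),), seed=9)
        rec, ann, _ = generate_recording(cfg)
        det = detect_r_peaks(rec.ecg, rec.fs)
        assert det.source == "detector"
        assert 56 <= det.r_ms.size <= 60          # ~58 beats fit in [1, 59] s
        for r in det.r_ms:
            assert np.min(np.abs(ann.r_ms - r)) <= 10.0

    def test_polarity_robust(self):
        cfg = SimConfig(duration_s=60.0, hr_profile=((0.0, 60.0),), seed=9)
        rec, _, _ = generate_recording(cfg)
        up = detect_r_peaks(rec.ecg, rec.fs)
        down = detect_r_peaks(-rec.ecg, rec.fs)
        assert up.r_ms.size == down.r_ms.size

    def test_flat_signal_gives_empty_stream(self, caplog):
        with caplog.at_level("WARNING"):
            det = detect_r_peaks(np.zeros(2000), FS)
        assert det.r_ms.size == 0


class TestQ:
    def test_q_trough_found_at_known_offset(self):
        cfg = SimConfig(duration_s=30.0, hr_profile=((0.0, 60.0),), seed=2,
                        q_offset_ms=-40.0)
        rec, ann, truth = generate_recording(cfg)
        from scg_beatkit import segment_beats as seg
        beats = seg(rec, ann)
        hits = [detect_q(b) for b in beats]
        for b, q in zip(beats, hits):
            assert q is not None
            assert q - b.r_time == pytest.approx(-40.0, abs=5.0)

    def test_monotone_pre_r_gives_missing(self):
        ecg = np.linspace(-1, 1, 400)
        beat = make_beat(np.zeros(400), ecg=ecg)
        assert detect_q(beat) is None

    def test_later_of_two_minima_wins(self):
        ecg = gauss_signal([(940.0, 5.0, -0.3), (970.0, 5.0, -0.2),
                            (1000.0, 8.0, 1.0)])
        beat = make_beat(np.zeros_like(ecg), ecg=ecg)
        q = detect_q(beat)
        assert q == pytest.approx(970.0, abs=5.0)


class TestTe:
    def test_tangent_method_recovers_t_end(self):
        cfg = SimConfig(duration_s=60.0, hr_profile=((0.0, 60.0),), seed=3)
        rec, ann, truth = generate_recording(cfg)
        from scg_beatkit import segment_beats as seg
        beats = seg(rec, ann)
        errs = []
        for b, (_, row) in zip(beats, truth.iterrows()):
            te = detect_te(b)
            assert te is not None
            errs.append(te - (row["te_ms"] - row["r_ms"]))
        assert np.max(np.abs(errs)) <= 15.0

    def test_trapezium_method_is_plausible(self):
        cfg = SimConfig(duration_s=30.0, hr_profile=((0.0, 60.0),), seed=3)
        rec, ann, truth = generate_recording(cfg)
        from scg_beatkit import segment_beats as seg
        beats = seg(rec, ann)
        te = detect_te(beats[3], TeConfig(method="trapezium"))
        want = truth["te_ms"].iloc[3] - truth["r_ms"].iloc[3]
        assert te is not None and abs(te - want) <= 30.0

    def test_flat_ecg_after_qrs_gives_missing(self):
        ecg = gauss_signal([(1000.0, 8.0, 1.0)])      # QRS only, no T wave
        beat = make_beat(np.zeros_like(ecg), ecg=ecg)
        assert detect_te(beat) is None

    def test_out_of_band_te_coerced_to_missing(self):
        cfg = SimConfig(duration_s=30.0, hr_profile=((0.0, 60.0),), seed=3)
        rec, ann, _ = generate_recording(cfg)
        from scg_beatkit import segment_beats as seg
        beats = seg(rec, ann)
        narrow = TeConfig(plausible_ms=(150.0, 300.0))   # true Te ~ 380 ms
        assert detect_te(beats[3], narrow) is None
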