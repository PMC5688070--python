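import numpy as np
import pytest

from scg_beatkit import (bandpass_scg, detect_fiducials,
                         find_ac_mo, find_icp, find_inflection, find_irp,
                         find_mc_ao, irp_candidate,
                         refine_hires, segment_beats, screen_beat)
from scg_beatkit.config import PipelineConfig
from scg_beatkit.fiducial_detect import _sinc_interp
from scg_beatkit.preprocess import annotate_beats
from scg_beatkit.synthetic_gen import _BeatModel, _refine_inflection
from conftest import gauss_signal, make_beat

FS = 200.0


def beat_from_bumps(bumps, rri=1000.0):
    scg = gauss_signal([(1000.0 + c, s, a) for c, s, a in bumps],
                       duration_ms=1000.0 + rri)
    return make_beat(scg, r_time=1000.0, rri=rri), scg


class TestICP:
    def test_unique_trough_with_close_reference(self):
        beat, _ = beat_from_bumps([(48.0, 5.0, -8.0)])
        icp = find_icp(beat, ref_rdelay=50.0)
        assert icp is not None and icp.rdelay == pytest.approx(48.0, abs=3)
        assert icp.amplitude < 0

    def test_reference_rule_rejects_distant_trough(self):
        beat, _ = beat_from_bumps([(48.0, 5.0, -8.0)])
        assert find_icp(beat, ref_rdelay=10.0) is None

    def test_bootstrap_takes_deepest_minimum(self):
        beat, _ = beat_from_bumps([(40.0, 4.0, -8.0), (60.0, 4.0, -5.0)])
        icp = find_icp(beat, ref_rdelay=None)
        assert icp.rdelay == pytest.approx(40.0, abs=3)

    def test_no_minimum_in_window(self):
        beat, _ = beat_from_bumps([(150.0, 5.0, -8.0)])   # outside S1si
        assert find_icp(beat, None) is None


class TestMCAO:
    def test_amplitude_rule_skips_spurious_peak(self):
        # trough -10 mg at 50 ms; the first peak after it rises only 1 mg
        # (fails the 0.7*|ICP_d| = 7 mg rule and is skipped), the next rises
        # 9 mg and becomes AO; MC symmetric on the other side
        profile = {25: -3.0, 30: -2.0, 35: 4.0, 40: -4.0, 45: -8.0,
                   50: -10.0, 55: -9.3, 60: -9.0, 65: -9.5, 70: -4.0,
                   75: -1.0, 80: -3.0, 85: -5.0}
        scg = np.zeros(600)
        for ms, v in profile.items():
            scg[int((1000 + ms) / 5)] = v
        beat = make_beat(scg, r_time=1000.0)
        icp = find_icp(beat, None)
        assert icp.rdelay == pytest.approx(50.0, abs=1)
        mc, ao = find_mc_ao(beat, icp)
        assert ao is not None and ao.cftp - beat.r_time == pytest.approx(75.0, abs=1)
        assert mc is not None and mc.cftp - beat.r_time == pytest.approx(35.0, abs=1)

    def test_no_peak_and_no_history_gives_missing(self):
        beat, _ = beat_from_bumps([(48.0, 5.0, -8.0)])    # lone trough
        icp = find_icp(beat, None)
        mc, ao = find_mc_ao(beat, icp)
        assert mc is None and ao is None

    def test_shoulder_recovered_as_inflection_on_clean_beat(self):
        # MC rendered as a shoulder on the ICP downstroke: the peak rule finds
        # nothing and the inflection fallback recovers it within +/-5 ms
        model = _BeatModel([(45.0, 6.5, -12.0), (62.0, 6.5, 8.0),
                            (37.0, 3.0, 3.0)])
        t = np.arange(0.0, 2000.0, 5.0)
        scg = model(t - 1000.0)
        beat = make_beat(scg, r_time=1000.0)
        icp = find_icp(beat, None)
        truth = _refine_inflection(model, 37.0)
        mc, ao = find_mc_ao(beat, icp, mc_history=[30.0, 31.0, 30.5],
                            ao_history=[62.0], scg_full=scg)
        assert mc is not None and mc.morphology == "inflection"
        assert mc.rdelay == pytest.approx(truth, abs=5.0)
        assert ao is not None and ao.morphology == "peak"


class TestIRP:
    def test_prominence_rule(self):
        # D = D1 + D2 < 7 mg -> rejected even though a peak exists
        beat, _ = beat_from_bumps([(375.0, 6.0, 3.0), (364.0, 6.0, -1.5),
                                   (386.0, 6.0, -1.0)])
        assert irp_candidate(beat, te_rdelay=380.0) is None
        beat, _ = beat_from_bumps([(375.0, 6.0, 6.0), (364.0, 6.0, -4.0),
                                   (386.0, 6.0, -4.0)])
        irp = irp_candidate(beat, te_rdelay=380.0)
        assert irp is not None and irp.d >= 7.0

    def test_reference_congruency(self):
        beat, _ = beat_from_bumps([(340.0, 6.0, 8.0), (329.0, 6.0, -4.0),
                                   (351.0, 6.0, -4.0)])
        ok = find_irp(beat, te_rdelay=340.0, history=[(0, 330.0)])
        assert ok is not None and abs(ok.rdelay - 330.0) <= 20.0
        miss = find_irp(beat, te_rdelay=340.0, history=[(0, 310.0)])
        assert miss is None

    def test_lookahead_requires_stable_rri(self):
        beat, _ = beat_from_bumps([(340.0, 6.0, 8.0), (329.0, 6.0, -4.0),
                                   (351.0, 6.0, -4.0)], rri=800.0)
        la_bad = [(800.0, None), (850.0, 338.0), (1000.0, 339.0)]
        assert find_irp(beat, 340.0, history=[], lookahead=la_bad) is None
        la_ok = [(800.0, None), (850.0, 338.0), (900.0, 339.0)]
        assert find_irp(beat, 340.0, history=[], lookahead=la_ok) is not None

    def test_missing_te_gives_missing_irp(self):
        beat, _ = beat_from_bumps([(340.0, 6.0, 8.0)])
        assert find_irp(beat, te_rdelay=None, history=[(0, 340.0)]) is None


class TestACMO:
    def _irp_beat(self):
        beat, scg = beat_from_bumps([
            (353.0, 5.0, 5.0),        # AC, 22 ms before IRP
            (364.0, 5.0, -4.0),
            (371.0, 2.5, 4.5),        # spurious peak 6 ms after AC... gap 4 from IRP
            (375.0, 5.0, 8.0),        # IRP
            (393.0, 5.0, -5.0),       # MO, 18 ms after
        ])
        irp = irp_candidate(beat, te_rdelay=380.0)
        assert irp is not None and irp.rdelay == pytest.approx(375.0, abs=3)
        return beat, irp

    def test_gap_scan_skips_too_close_peaks(self):
        beat, irp = self._irp_beat()
        ac, mo = find_ac_mo(beat, irp)
        assert ac is not None
        assert irp.rdelay - (ac.cftp - beat.r_time) == pytest.approx(22.0, abs=4)
        assert mo is not None
        assert (mo.cftp - beat.r_time) - irp.rdelay == pytest.approx(18.0, abs=4)
        assert mo.morphology == "trough"

    def test_mo_beyond_30ms_is_missing(self):
        beat, scg = beat_from_bumps([(353.0, 5.0, 5.0), (364.0, 5.0, -4.0),
                                     (375.0, 5.0, 8.0), (411.0, 5.0, -5.0)])
        irp = irp_candidate(beat, te_rdelay=380.0)
        ac, mo = find_ac_mo(beat, irp)
        assert ac is not None and mo is None


class TestInflection:
    def test_cubic_inflection_located(self):
        t = np.arange(-50, 50, 5.0)
        x = (t - 3.0) ** 3 / 1e3
        got = find_inflection(x, dt_ms=5.0, polarity="trough-like", t0_ms=-50.0)
        assert got == pytest.approx(3.0, abs=5.0)
        got = find_inflection(-x, dt_ms=5.0, polarity="peak-like", t0_ms=-50.0)
        assert got == pytest.approx(3.0, abs=5.0)

    def test_strictly_convex_segment_has_none(self):
        t = np.arange(-50, 50, 5.0)
        assert find_inflection(t ** 2, 5.0, "peak-like") is None
        assert find_inflection(t ** 2, 5.0, "trough-like") is None


class TestHires:
    def test_off_grid_sinusoid_crest_within_1ms(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            f = rng.uniform(5.0, 40.0)
            t0 = rng.uniform(0.95, 1.05)
            t = np.arange(0, 2.0, 1 / FS)
            x = np.cos(2 * np.pi * f * (t - t0))
            cftp = round(t0 * FS) * 1000.0 / FS
            hr, refined = refine_hires(x, cftp, "max", FS)
            assert refined and abs(hr - t0 * 1000.0) <= 1.0

    def test_on_sample_extremum_is_unmoved(self):
        t = np.arange(0, 2.0, 1 / FS)
        x = np.cos(2 * np.pi * 10.0 * (t - 1.0))    # crest exactly at sample 200
        hr, refined = refine_hires(x, 1000.0, "max", FS)
        assert refined and hr == pytest.approx(1000.0, abs=1e-9)

    def test_interpolation_identity_at_sample_instants(self):
        from scipy import signal as sg
        rng = np.random.default_rng(22)
        x = sg.sosfiltfilt(sg.butter(4, [5, 40], btype="bandpass", fs=FS,
                                     output="sos"), rng.standard_normal(500))
        ks = np.arange(200, 221)
        y = _sinc_interp(x, 210, ks * 5.0, FS)
        assert np.max(np.abs(y - x[ks])) <= 1e-9 * np.max(np.abs(x))

    def test_never_moves_more_than_5ms(self):
        from scipy import signal as sg
        rng = np.random.default_rng(23)
        x = sg.sosfiltfilt(sg.butter(4, [5, 40], btype="bandpass", fs=FS,
                                     output="sos"), rng.standard_normal(2000))
        for k in rng.integers(100, 1900, size=40):
            cftp = k * 5.0
            for kind in ("max", "min"):
                hr, _ = refine_hires(x, float(cftp), kind, FS)
                assert abs(hr - cftp) <= 5.0

    def test_clipped_window_flagged_unrefined(self):
        x = np.zeros(80)
        hr, refined = refine_hires(x, 100.0, "max", FS)
        assert hr == 100.0 and not refined


@pytest.fixture(scope="module")
def detected(short_recording):
    record, ann, truth = short_recording
    cfg = PipelineConfig()
    scg_f = bandpass_scg(record.scg, record.fs)
    beats = segment_beats(record, ann, scg_filtered=scg_f)
    valid = [screen_beat(b)[0].is_valid for b in beats]
    annotate_beats(beats, cfg)
    fid = detect_fiducials(beats, valid, cfg, scg_full=scg_f)
    return beats, valid, fid


class TestSequence:
    def test_anchor_containment(self, detected):
        beats, valid, fid = detected
        for b, ok, res in zip(beats, valid, fid):
            if not ok:
                continue
            if res["icp"] is not None:
                assert 25.0 <= res["icp"].rdelay <= 75.0
            if res["irp"] is not None:
                assert abs(res["irp"].rdelay - b.te_rdelay) <= 30.0 + 2.5

    def test_fp_ordering_and_window_bounds(self, detected):
        beats, valid, fid = detected
        n_all4 = 0
        for res in fid:
            fps = [res[k] for k in ("mc", "ao", "ac", "mo")]
            if any(f is None for f in fps):
                continue
            n_all4 += 1
            mc, ao, ac, mo = (f.rdelay for f in fps)
            assert mc < ao < ac < mo
            assert ao - mc <= 100.0 and mo - ac <= 70.0
        assert n_all4 > 100

    def test_hires_stays_within_5ms_of_coarse(self, detected):
        _, _, fid = detected
        for res in fid:
            for k in ("mc", "ao", "ac", "mo"):
                fp = res[k]
                if fp is not None and fp.hrftp is not None:
                    assert abs(fp.hrftp - fp.cftp) <= 5.0 + 1e-9

    def test_detection_is_deterministic(self, short_recording):
        record, ann, truth = short_recording
        cfg = PipelineConfig()
        scg_f = bandpass_scg(record.scg, record.fs)
        beats = segment_beats(record, ann, scg_filtered=scg_f)
        valid = [screen_beat(b)[0].is_valid for b in beats]
        annotate_beats(beats, cfg)
        a = detect_fiducials(beats, valid, cfg, scg_full=scg_f)
        b = detect_fiducials(beats, valid, cfg, scg_full=scg_f)
        for ra, rb in zip(a, b):
            for k in ("mc", "ao", "ac", "mo"):
                fa, fb = ra[k], rb[k]
                assert (fa is None) == (fb is None)
                if fa is not None:
                    assert fa.hrftp == fb.hrftp and fa.cftp == fb.cftp
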