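"""Synthetic ECG+SCG recordings with analytically known fiducial ground truth.

The generator emulates the features of sleep seismocardiography that the
detection pipeline must survive: hours-capable records at 200 Hz, heart rate
trajectories anywhere in 40-120 bpm, a systolic (MC-ICP-AO) and a diastolic
(AC-IRP-MO) vibration complex of a few milli-g, respiratory modulation of
amplitudes and delays, a configurable fraction of beats whose MC appears as
an inflection ("shoulder") instead of a peak, band-limited instrument noise,
and movement artifacts 10-100x the SCG amplitude.

Each complex is a superposition of signed Gaussian bumps, and the rendered
record is confined to the 5-40 Hz analysis band (>=95% of signal power) by a
gentle zero-phase low-pass.  Ground truth is taken from the *rendered*
noise-free waveform: every true fiducial time is the numerically located
extremum (or curvature zero crossing) of the sinc-upsampled record, so truth
and signal are consistent by construction and known to sub-millisecond
precision.

Systolic delays are nearly heart-rate independent; the T-wave end - and with
it the whole diastolic complex - shortens with the RR interval
(Te ~ 240 + 0.14*RRI ms), which keeps the second-sound envelope peak inside
the 300-480 ms morphology window over the full 40-120 bpm span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from ._timing import ms_to_samples
from .config import ConfigurationError
from .record_io import AnnotationStream, Record, TRUTH_COLUMNS


@dataclass
class ArtifactSpec:
    """Movement-artifact injection: rate = target fraction of flagged beats."""
    rate: float = 0.1
    amp_range_mg: Tuple[float, float] = (60.0, 1000.0)
    duration_range_s: Tuple[float, float] = (0.2, 3.0)
    carrier_hz: float = 15.0
    taper_s: float = 0.02            # short edge ramps keep the truth flag crisp
    flag_level_mg: float = 30.0      # beat flagged when injected amplitude exceeds this


@dataclass
class SimConfig:
    duration_s: float = 300.0
    fs: float = 200.0
    # piecewise-linear heart-rate trajectory: (time_s, bpm) control points
    hr_profile: Sequence[Tuple[float, float]] = ((0.0, 60.0),)
    resp_rate_hz: float = 0.25
    resp_mod_frac: float = 0.15      # amplitude modulation of the systolic complex
    resp_mod_diff: float = 0.05      # diastolic complex is modulated this much less
    resp_delay_mod_ms: float = 3.0   # sinusoidal FP-delay modulation
    rsa_frac: float = 0.03           # respiratory sinus arrhythmia on RRI
    delay_jitter_ms: float = 0.4     # white jitter on FP delays
    # fiducial geometry (ms, relative to R unless noted)
    icp_rdelay_ms: float = 45.0
    mc_offset_ms: float = -15.0      # MC bump centre relative to ICP
    ao_offset_ms: float = 17.0       # AO bump centre relative to ICP
    te_intercept_ms: float = 240.0   # Te ~ intercept + slope * RRI
    te_slope: float = 0.14
    irp_offset_ms: float = -5.0      # IRP relative to Te
    ac_offset_ms: float = -22.0      # AC bump centre relative to IRP
    mid_offset_ms: float = -11.0     # trough between AC and IRP
    mo_offset_ms: float = 16.0       # MO relative to IRP
    q_offset_ms: float = -35.0
    t_sigma_ms: float = 35.0         # Te_true = T centre + 2*t_sigma (tangent rule)
    # component amplitudes (mg) and widths (ms)
    amp_as_mg: float = 0.0           # optional atrial-systole wave before the S1 complex
    as_rdelay_ms: float = 19.0
    as_sigma_ms: float = 6.0
    amp_mc_mg: float = 5.0
    amp_icp_mg: float = 12.0
    amp_ao_mg: float = 8.0
    amp_ac_mg: float = 5.0
    amp_mid_mg: float = 4.5
    amp_irp_mg: float = 8.0
    amp_mo_mg: float = 5.5
    sigma_sys_ms: float = 6.5
    sigma_dia_ms: float = 5.5
    # inflection-morphology beats: MC rendered as a shoulder on the ICP flank
    inflection_frac: float = 0.06
    shoulder_ratio: float = 0.4      # shoulder bump amplitude / ICP amplitude
    shoulder_offset_ms: float = -10.0
    shoulder_sigma_ms: float = 5.0
    noise_rms_mg: float = 0.3
    ecg_noise_rms: float = 0.005
    artifact_spec: Optional[ArtifactSpec] = None
    seed: int = 0

    def validate(self) -> None:
        hrs = [h for _, h in self.hr_profile]
        if not hrs or min(hrs) < 40.0 - 1e-9 or max(hrs) > 120.0 + 1e-9:
            raise ConfigurationError("hr_profile must stay within 40-120 bpm")
        if self.resp_rate_hz > 0:
            if 1.0 / self.resp_rate_hz < 2 * 60.0 / max(hrs):
                raise ConfigurationError("respiratory period shorter than 2 beats")
        if self.duration_s < 10.0:
            raise ConfigurationError("duration must be at least 10 s")


# ---------------------------------------------------------------------------
# Per-beat continuous waveform model

def _gauss(t, c, s, a):
    return a * np.exp(-0.5 * ((t - c) / s) ** 2)


class _BeatModel:
    """Analytic noise-free SCG of one beat (time in ms relative to R)."""

    def __init__(self, bumps: List[Tuple[float, float, float]]):
        self.bumps = bumps       # (centre, sigma, amplitude)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, s, a in self.bumps:
            out += _gauss(t, c, s, a)
        return out

    def d1(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, s, a in self.bumps:
            out += _gauss(t, c, s, a) * (-(t - c) / s ** 2)
        return out

    def d2(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, s, a in self.bumps:
            out += _gauss(t, c, s, a) * (((t - c) ** 2 - s ** 2) / s ** 4)
        return out


def _refine_extremum(model: _BeatModel, centre: float, kind: str,
                     halfwidth: float = 8.0) -> float:
    """Sub-ms extremum of the continuous model near ``centre`` (parabolic)."""
    t = np.arange(centre - halfwidth, centre + halfwidth, 0.05)
    y = model(t)
    i = int(np.argmax(y) if kind == "max" else np.argmin(y))
    i = min(max(i, 1), t.size - 2)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    off = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(t[i] + np.clip(off, -1, 1) * 0.05)


def _refine_inflection(model: _BeatModel, centre: float,
                       halfwidth: float = 8.0) -> Optional[float]:
    """+to- zero crossing of the curvature nearest ``centre`` (the shoulder)."""
    t = np.arange(centre - halfwidth, centre + halfwidth, 0.05)
    d2 = model.d2(t)
    best, best_dist = None, np.inf
    for i in range(t.size - 1):
        if d2[i] > 0 and d2[i + 1] < 0:
            frac = d2[i] / (d2[i] - d2[i + 1])
            tc = t[i] + frac * 0.05
            if abs(tc - centre) < best_dist:
                best, best_dist = float(tc), abs(tc - centre)
    return best


def _signal_feature(scg: np.ndarray, fs: float, centre_ms: float, kind: str,
                    halfwidth: float = 8.0) -> Optional[float]:
    """Sub-ms fiducial feature of the *rendered* noise-free waveform.

    The band-limited record is sinc-upsampled on a 0.1 ms grid around
    ``centre_ms``; ``kind`` is ``max``/``min`` (parabolic-refined extremum)
    or ``inflection`` (+to- curvature zero crossing nearest the centre).
    """
    from .fiducial_detect import _sinc_interp
    k0 = ms_to_samples(centre_ms, fs)
    if k0 - 50 < 0 or k0 + 50 >= scg.size:
        return None
    t = np.arange(centre_ms - halfwidth, centre_ms + halfwidth + 0.05, 0.1)
    y = _sinc_interp(scg, k0, t, fs)
    if kind in ("max", "min"):
        i = int(np.argmax(y) if kind == "max" else np.argmin(y))
        i = min(max(i, 1), t.size - 2)
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        off = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
        return float(t[i] + np.clip(off, -1, 1) * 0.1)
    d2 = np.diff(y, 2)
    best, best_dist = None, np.inf
    for i in range(d2.size - 1):
        if d2[i] > 0 and d2[i + 1] < 0:
            frac = d2[i] / (d2[i] - d2[i + 1])
            tc = t[i + 1] + frac * 0.1
            if abs(tc - centre_ms) < best_dist:
                best, best_dist = float(tc), abs(tc - centre_ms)
    return best


# ---------------------------------------------------------------------------
# Recording generation

def _r_times(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """R-peak times (ms) from the commanded HR trajectory + RSA."""
    ts = np.array([t for t, _ in cfg.hr_profile], dtype=float)
    hrs = np.array([h for _, h in cfg.hr_profile], dtype=float)
    out = []
    t = 1.0                                  # leave room for pre-R window + guard
    while True:
        hr = float(np.interp(t, ts, hrs))
        rri_s = 60.0 / hr
        if cfg.resp_rate_hz > 0 and cfg.rsa_frac > 0:
            rri_s *= 1.0 + cfg.rsa_frac * np.sin(2 * np.pi * cfg.resp_rate_hz * t)
        if t + rri_s > cfg.duration_s - 1.0:
            out.append(t)
            break
        out.append(t)
        t += rri_s
    return np.asarray(out) * 1000.0


def generate_recording(cfg: SimConfig
                       ) -> Tuple[Record, AnnotationStream, pd.DataFrame]:
    """Render a recording and its ground-truth table; bit-reproducible per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    t_ms = np.arange(n) * 1000.0 / fs
    ecg = np.zeros(n)
    scg = np.zeros(n)

    r_ms = _r_times(cfg, rng)
    n_beats = r_ms.size - 1
    rows = []

    for i in range(n_beats):
        r = r_ms[i]
        rri = r_ms[i + 1] - r
        phase = 2 * np.pi * cfg.resp_rate_hz * r / 1000.0
        amp_s = 1.0 + cfg.resp_mod_frac * np.sin(phase)
        amp_d = 1.0 + (cfg.resp_mod_frac - cfg.resp_mod_diff) * np.sin(phase)
        jit_s = (cfg.resp_delay_mod_ms * np.sin(phase + 1.0)
                 + rng.normal(0.0, cfg.delay_jitter_ms))
        jit_d = (cfg.resp_delay_mod_ms * np.sin(phase + 2.0)
                 + rng.normal(0.0, cfg.delay_jitter_ms))
        inflect = bool(rng.random() < cfg.inflection_frac)

        icp = cfg.icp_rdelay_ms + jit_s
        ao_c = icp + cfg.ao_offset_ms
        te_true = cfg.te_intercept_ms + cfg.te_slope * rri + jit_d
        irp = te_true + cfg.irp_offset_ms
        ac_c, mid_c, mo_c = (irp + cfg.ac_offset_ms, irp + cfg.mid_offset_ms,
                             irp + cfg.mo_offset_ms)

        bumps = [(cfg.as_rdelay_ms, cfg.as_sigma_ms, cfg.amp_as_mg * amp_s),
                 (icp, cfg.sigma_sys_ms, -cfg.amp_icp_mg * amp_s),
                 (ao_c, cfg.sigma_sys_ms, cfg.amp_ao_mg * amp_s),
                 (ac_c, cfg.sigma_dia_ms, cfg.amp_ac_mg * amp_d),
                 (mid_c, cfg.sigma_dia_ms, -cfg.amp_mid_mg * amp_d),
                 (irp, cfg.sigma_dia_ms, cfg.amp_irp_mg * amp_d),
                 (mo_c, cfg.sigma_dia_ms, -cfg.amp_mo_mg * amp_d)]
        if inflect:
            mc_c = icp + cfg.shoulder_offset_ms
            bumps.append((mc_c, cfg.shoulder_sigma_ms,
                          cfg.shoulder_ratio * cfg.amp_icp_mg * amp_s))
        else:
            mc_c = icp + cfg.mc_offset_ms
            bumps.append((mc_c, cfg.sigma_sys_ms, cfg.amp_mc_mg * amp_s))
        model = _BeatModel(bumps)

        # render SCG bumps over +/-5 sigma
        for c, s, a in bumps:
            a_idx = max(0, ms_to_samples(r + c - 5 * s, fs))
            b_idx = min(n, ms_to_samples(r + c + 5 * s, fs) + 1)
            scg[a_idx:b_idx] += _gauss(t_ms[a_idx:b_idx], r + c, s, a)

        # ECG: P, Q, R, S, T
        tc = te_true - 2.0 * cfg.t_sigma_ms
        for c, s, a in ((-160.0, 20.0, 0.10), (cfg.q_offset_ms, 7.0, -0.12),
                        (0.0, 8.0, 1.0), (25.0, 8.0, -0.15),
                        (tc, cfg.t_sigma_ms, 0.30 * (1 + 0.05 * np.sin(phase)))):
            a_idx = max(0, ms_to_samples(r + c - 5 * s, fs))
            b_idx = min(n, ms_to_samples(r + c + 5 * s, fs) + 1)
            ecg[a_idx:b_idx] += _gauss(t_ms[a_idx:b_idx], r + c, s, a)

        rows.append({"r_ms": r, "rri_ms": rri,
                     "q_ms": r + cfg.q_offset_ms, "te_ms": r + te_true,
                     "artifact": 0,
                     "mc_morph": "inflection" if inflect else "peak",
                     "_model": model,
                     "_centres": {"mc": mc_c, "ao": ao_c, "ac": ac_c,
                                  "mo": mo_c, "icp": icp, "irp": irp}})

    # confine rendered energy to the 5-40 Hz analysis band (zero phase; the
    # extrema move by well under a millisecond and truth is taken from the
    # filtered waveform below, so truth and signal remain consistent)
    sos_lp = signal.butter(6, 45.0, btype="lowpass", fs=fs, output="sos")
    scg = signal.sosfiltfilt(sos_lp, scg)

    # ground truth: the fiducial features of the rendered noise-free waveform
    for row in rows:
        r = row.pop("_r", row["r_ms"])
        centres = row.pop("_centres")
        model = row.pop("_model")
        kinds = {"mc": "max", "ao": "max", "ac": "max", "mo": "min",
                 "icp": "min", "irp": "max"}
        if row["mc_morph"] == "inflection":
            kinds["mc"] = "inflection"
        for lab, kind in kinds.items():
            t = _signal_feature(scg, fs, r + centres[lab], kind)
            if t is None:          # clipped window or degenerate shoulder
                rel = (_refine_inflection(model, centres[lab])
                       if kind == "inflection" else
                       _refine_extremum(model, centres[lab], kind))
                t = r + (centres[lab] if rel is None else rel)
            row[f"{lab}_ms"] = float(t)
        if not (row["mc_ms"] < row["ao_ms"] < row["ac_ms"] < row["mo_ms"]):
            raise RuntimeError("generated fiducial ordering violated")

    if cfg.noise_rms_mg > 0:
        white = rng.standard_normal(n)
        sos = signal.butter(4, [5.0, 40.0], btype="bandpass", fs=fs, output="sos")
        band = signal.sosfiltfilt(sos, white)
        scg += band * (cfg.noise_rms_mg / np.std(band))
    if cfg.ecg_noise_rms > 0:
        ecg += rng.normal(0.0, cfg.ecg_noise_rms, n)

    record = Record(ecg=ecg, scg=scg, fs=fs)
    ann = AnnotationStream(r_ms=r_ms, validity=np.ones(r_ms.size, bool),
                           source="file")
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if cfg.artifact_spec is not None and cfg.artifact_spec.rate > 0:
        record, truth = inject_artifacts(record, truth, cfg.artifact_spec,
                                         seed=cfg.seed + 1)
    return record, ann, truth


# ---------------------------------------------------------------------------
# Artifact injection

def inject_artifacts(record: Record, truth: pd.DataFrame, spec: ArtifactSpec,
                     seed: int = 0) -> Tuple[Record, pd.DataFrame]:
    """Add movement-artifact bursts; flag corrupted beats in the truth table.

    Bursts are Tukey-windowed oscillations (peak 60-1000 mg, 0.2-3 s) placed
    at randomly chosen beats until the target fraction of beats is flagged.
    A beat is flagged when the injected amplitude inside its nominal window
    exceeds ``flag_level_mg``.  ``rate=0`` returns the inputs unchanged.
    """
    truth = truth.copy()
    scg = record.scg.copy()
    n = scg.size
    fs = record.fs
    t_ms = np.arange(n) * 1000.0 / fs
    n_beats = len(truth)
    if spec.rate <= 0 or n_beats == 0:
        return Record(ecg=record.ecg.copy(), scg=scg, fs=fs,
                      start_time=record.start_time, meta=dict(record.meta)), truth
    rng = np.random.default_rng(seed)
    target = int(round(spec.rate * n_beats))
    added = np.zeros(n)
    r = truth["r_ms"].to_numpy()
    rri = truth["rri_ms"].to_numpy()
    starts = r - 200.0
    ends = starts + rri
    flagged = np.zeros(n_beats, dtype=bool)
    attempts = 0
    while flagged.sum() < target and attempts < 50 * max(target, 1):
        attempts += 1
        j = int(rng.integers(0, n_beats))
        dur = float(rng.uniform(*spec.duration_range_s)) * 1000.0
        amp = float(np.exp(rng.uniform(np.log(spec.amp_range_mg[0]),
                                       np.log(spec.amp_range_mg[1]))))
        centre = r[j] + float(rng.uniform(0.0, rri[j]))
        ph = float(rng.uniform(0, 2 * np.pi))
        a_idx = max(0, ms_to_samples(centre - dur / 2, fs))
        b_idx = min(n, ms_to_samples(centre + dur / 2, fs) + 1)
        if b_idx - a_idx < 5:
            continue
        tt = t_ms[a_idx:b_idx]
        taper = min(spec.taper_s * 1000.0, dur / 2)
        env = np.minimum(1.0, np.minimum((tt - tt[0]) / taper,
                                         (tt[-1] - tt) / taper))
        env = np.clip(env, 0.0, 1.0)
        burst = amp * env * np.cos(2 * np.pi * spec.carrier_hz * tt / 1000.0 + ph)
        added[a_idx:b_idx] += burst
        # flag beats whose nominal window now holds injected amplitude > level
        lo = np.searchsorted(ends, tt[0], side="right")
        hi = np.searchsorted(starts, tt[-1], side="left")
        for k in range(max(0, lo), min(n_beats, hi)):
            ka = max(0, ms_to_samples(starts[k], fs))
            kb = min(n, ms_to_samples(ends[k], fs))
            if ka < kb and np.max(np.abs(added[ka:kb])) > spec.flag_level_mg:
                flagged[k] = True
    truth["artifact"] = flagged.astype(int)
    return Record(ecg=record.ecg.copy(), scg=scg + added, fs=fs,
                  start_time=record.start_time, meta=dict(record.meta)), truth
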