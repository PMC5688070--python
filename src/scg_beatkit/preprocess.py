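"""Signal conditioning and ECG landmarks.

Covers the steps upstream of the SCG pattern analysis: zero-phase 5-40 Hz
band-pass of the SCG, splitting the record into beats pinned to the R peaks
(each beat runs from 200 ms before its R peak to 200 ms before the next one),
a fallback QRS detector for records that arrive without an annotation file,
and the two ECG landmarks the interval computation needs: the Q trough and
the end of the T wave (Te), which centres the diastolic search window.

Because late diastole at high heart rate crosses the nominal beat boundary
(a 120-bpm beat ends 300 ms after its R peak, before the second heart sound
has finished), every :class:`BeatSegment` also exposes an *extended* view of
both channels running up to the next R peak.  The extension contains no SCG
activity of the following beat - its systolic complex starts ~25 ms after
the next R - and is used by the envelope, Te and diastolic searches only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import signal

from ._extrema import local_minima
from ._timing import ms_to_samples, samples_to_ms
from .config import ConfigurationError, PipelineConfig, QConfig, TeConfig
from .record_io import AnnotationStream, Record

log = logging.getLogger(__name__)

PRE_R_MS = 200.0


@dataclass
class BeatSegment:
    """One heart beat: channels, timing and per-beat ECG landmarks."""

    index: int
    r_time: float              # ms
    rri: float                 # ms, to the next R
    start_time: float          # ms, r_time - 200
    end_time: float            # ms, next r_time - 200
    fs: float
    start_idx: int
    end_idx: int               # exclusive, nominal window
    ext_end_idx: int           # exclusive, extended window (up to next R)
    ecg: np.ndarray = field(repr=False, default=None)
    scg: np.ndarray = field(repr=False, default=None)
    ecg_ext: np.ndarray = field(repr=False, default=None)
    scg_ext: np.ndarray = field(repr=False, default=None)
    q_time: Optional[float] = None      # ms, absolute
    te_time: Optional[float] = None     # ms, absolute

    @property
    def q_rdelay(self) -> Optional[float]:
        return None if self.q_time is None else self.q_time - self.r_time

    @property
    def te_rdelay(self) -> Optional[float]:
        return None if self.te_time is None else self.te_time - self.r_time

    def idx_at(self, t_ms: float) -> int:
        """Index into the (extended) beat arrays of the sample nearest ``t_ms``."""
        return ms_to_samples(t_ms, self.fs) - self.start_idx

    def time_of(self, idx: int) -> float:
        """Absolute time in ms of beat-array index ``idx``."""
        return samples_to_ms(self.start_idx + idx, self.fs)

    def rdelay_of(self, idx: int) -> float:
        return self.time_of(idx) - self.r_time


def bandpass_scg(scg, fs: float, low: float = 5.0, high: float = 40.0,
                 order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-reverse) of the SCG.

    The effective response is the squared magnitude of an ``order``-pole
    band-pass; DC and drifts are removed and the phase shift is zero.
    """
    if fs <= 2.0 * high:
        raise ConfigurationError(f"fs={fs} must exceed twice the upper edge {high} Hz")
    x = np.asarray(scg, dtype=float)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if x.size <= 3 * (6 * order + 1):
        raise ConfigurationError("signal too short for stable zero-phase filtering")
    return signal.sosfiltfilt(sos, x)


def segment_beats(record: Record, annotations: AnnotationStream,
                  scg_filtered: Optional[np.ndarray] = None,
                  edge_guard_s: float = 0.5) -> List[BeatSegment]:
    """Split a record into beats pinned to consecutive valid R peaks.

    Windows are contiguous on the sample grid (a beat ends where the next one
    starts).  Beats whose nominal or extended window leaves the record, or
    enters the first/last ``edge_guard_s`` seconds (filter warm-up), are
    dropped with a logged reason.
    """
    fs = record.fs
    scg = record.scg if scg_filtered is None else np.asarray(scg_filtered, dtype=float)
    r = annotations.valid_r_ms
    if r.size < 2:
        log.warning("fewer than 2 valid R peaks: no beats segmented")
        return []
    guard = ms_to_samples(edge_guard_s * 1000.0, fs)
    starts = ms_to_samples(r - PRE_R_MS, fs)
    beats: List[BeatSegment] = []
    for i in range(r.size - 1):
        s0, s1 = int(starts[i]), int(starts[i + 1])
        ext1 = ms_to_samples(r[i + 1], fs)
        if r[i] < PRE_R_MS or s0 < guard:
            log.info("beat %d dropped: window before record/guard start", i)
            continue
        if ext1 > record.n - guard:
            log.info("beat %d dropped: window beyond record/guard end", i)
            continue
        beats.append(BeatSegment(
            index=len(beats),
            r_time=float(r[i]), rri=float(r[i + 1] - r[i]),
            start_time=float(r[i] - PRE_R_MS), end_time=float(r[i + 1] - PRE_R_MS),
            fs=fs, start_idx=s0, end_idx=s1, ext_end_idx=int(ext1),
            ecg=record.ecg[s0:s1], scg=scg[s0:s1],
            ecg_ext=record.ecg[s0:ext1], scg_ext=scg[s0:ext1],
        ))
    return beats


# ---------------------------------------------------------------------------
# Fallback R-peak detection (Pan-Tompkins-style energy detector)

def detect_r_peaks(ecg, fs: float) -> AnnotationStream:
    """Detect R peaks in an ECG; polarity-robust, ``source='detector'``.

    Used only when no annotation file is supplied; file annotations always
    take precedence.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("ECG must be at least 2 s long for R detection")
    if np.ptp(x) == 0 or np.std(x) < 1e-12:
        log.warning("flat ECG: no R peaks detected")
        return AnnotationStream(r_ms=np.empty(0), validity=np.empty(0, bool),
                                source="detector")
    sos = signal.butter(2, [5.0, min(20.0, 0.45 * fs)], btype="bandpass",
                        fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, x)
    energy = np.gradient(band) ** 2
    w = max(3, ms_to_samples(120.0, fs))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    height = 0.2 * np.percentile(integ, 99)
    locs, _ = signal.find_peaks(integ, height=height,
                                distance=max(1, ms_to_samples(250.0, fs)))
    half = ms_to_samples(80.0, fs)
    r_idx = []
    for p in locs:
        a, b = max(0, p - half), min(x.size, p + half + 1)
        r_idx.append(a + int(np.argmax(np.abs(band[a:b]))))
    r_idx = np.unique(r_idx)
    if r_idx.size > 1:
        keep = np.concatenate([[True], np.diff(r_idx) > ms_to_samples(200.0, fs)])
        r_idx = r_idx[keep]
    r_ms = samples_to_ms(r_idx, fs)
    return AnnotationStream(r_ms=np.atleast_1d(r_ms),
                            validity=np.ones(r_idx.size, dtype=bool),
                            source="detector")


# ---------------------------------------------------------------------------
# ECG landmarks

def detect_q(beat: BeatSegment, cfg: Optional[QConfig] = None) -> Optional[float]:
    """Q time (ms, absolute): last local ECG minimum in [R-80, R-8] ms.

    Returns ``None`` when the window holds no local minimum (e.g. a monotone
    rising pre-R ECG).  With several candidate minima the one closest to R
    wins.
    """
    cfg = cfg or QConfig()
    near, far = cfg.window_ms
    a = beat.idx_at(beat.r_time - far)
    b = beat.idx_at(beat.r_time - near)
    if a < 0 or b <= a + 1:
        return None
    seg = beat.ecg_ext[max(0, a - 1):b + 2]   # one-sample margin for edge extrema
    mins = local_minima(seg) + max(0, a - 1)
    mins = mins[(mins >= a) & (mins <= b)]
    if mins.size == 0:
        return None
    return beat.time_of(int(mins[-1]))


def detect_te(beat: BeatSegment, cfg: Optional[TeConfig] = None) -> Optional[float]:
    """T-wave end delay from R (ms) or ``None``.

    Default method: tangent - the steepest tangent on the T downslope is
    intersected with the isoelectric baseline.  Alternative: trapezium -
    maximise the area of the trapezium spanned by the steepest-slope point, a
    baseline reference point and the moving candidate.  Results outside the
    plausible (150, 500) ms band are coerced to missing.
    """
    cfg = cfg or TeConfig()
    fs = beat.fs
    dt = 1000.0 / fs
    # isoelectric baseline from a quiet pre-QRS stretch (clear of P and Q waves)
    b0, b1 = beat.idx_at(beat.r_time - 120.0), beat.idx_at(beat.r_time - 85.0)
    if b0 < 0 or b1 <= b0:
        return None
    baseline = float(np.median(beat.ecg_ext[b0:b1 + 1]))
    noise = float(np.median(np.abs(beat.ecg_ext[b0:b1 + 1] - baseline))) + 1e-12
    # T peak search, kept clear of the next beat's P wave
    t0 = beat.idx_at(beat.r_time + 120.0)
    t1 = beat.idx_at(beat.r_time + min(480.0, beat.rri - 180.0))
    n_ext = beat.ecg_ext.size
    t0, t1 = max(0, t0), min(n_ext - 1, t1)
    if t1 <= t0 + 3:
        return None
    seg = beat.ecg_ext[t0:t1 + 1] - baseline
    p = int(np.argmax(np.abs(seg)))
    amp = seg[p]
    if abs(amp) < max(10 * noise, 1e-9):
        return None                      # no discernible T wave
    sgn = np.sign(amp)
    # steepest downslope after the T peak
    d0 = t0 + p
    d1 = min(n_ext - 1, d0 + ms_to_samples(150.0, fs))
    if d1 <= d0 + 1:
        return None
    deriv = np.diff(beat.ecg_ext[d0:d1 + 1]) / dt
    # smooth the discrete derivative (~25 ms) so noise does not bias the
    # steepest-slope pick toward spuriously steep samples
    w = max(1, ms_to_samples(25.0, fs))
    deriv = np.convolve(deriv, np.ones(w) / w, mode="same")
    s = int(np.argmin(sgn * deriv))
    slope = float(deriv[s])
    if sgn * slope >= 0 or abs(slope) < 1e-12:
        return None
    ts_idx = d0 + s
    # the diff sample sits between ts_idx and ts_idx+1
    y_s = 0.5 * (float(beat.ecg_ext[ts_idx]) + float(beat.ecg_ext[min(ts_idx + 1,
                                                                      n_ext - 1)]))
    t_s = beat.time_of(ts_idx) + 0.5 * dt
    if cfg.method == "tangent":
        te = t_s + (baseline - y_s) / slope
    elif cfg.method == "trapezium":
        # reference point ~60 ms past the steepest slope: close enough to keep
        # the area maximum near the true T end, far enough to sit on baseline
        xr_idx = min(n_ext - 1, ts_idx + ms_to_samples(60.0, fs))
        idxs = np.arange(ts_idx, xr_idx + 1)
        y = beat.ecg_ext[idxs]
        x_r = beat.time_of(int(xr_idx))
        x_i = beat.start_idx * dt + idxs * dt
        area = 0.5 * (y_s - y) * (2 * x_r - x_i - t_s)
        te = float(x_i[int(np.argmax(sgn * area))])
    else:
        raise ConfigurationError(f"unknown Te method {cfg.method!r}")
    te_rdelay = te - beat.r_time
    lo, hi = cfg.plausible_ms
    if not (lo < te_rdelay < hi):
        return None
    return te_rdelay


def annotate_beats(beats: List[BeatSegment], cfg: PipelineConfig) -> None:
    """Fill ``q_time`` / ``te_time`` of each beat in place."""
    for b in beats:
        q = detect_q(b, cfg.q)
        b.q_time = q
        te = detect_te(b, cfg.te)
        b.te_time = None if te is None else b.r_time + te
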