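"""SCG fiducial-point detection (valve events MC, AO, AC, MO).

The search is anchored on the two clearest displacements of the SCG
waveform: the isovolumic contraction point (ICP), the deepest trough of the
S1 interval [R+25, R+75] ms, and the isovolumic relaxation point (IRP), the
most prominent peak of the 60 ms interval centred on the T-wave end.  MC and
AO are the first sufficiently tall peaks flanking the ICP; AC is the first
peak 10-40 ms before the IRP and MO the first trough 10-30 ms after it.
When the expected peak or trough degenerates into a shoulder (an inflection
of the waveform, seen in roughly 6% of beats), the inflection point stands
in for the fiducial point.

Detections are first made on the native 5 ms grid (CFTP) and then refined to
a 1 ms grid (HRFTP) by Whittaker-Shannon sinc interpolation of a 101-sample
window, re-locating the feature inside a 10 ms window centred on the coarse
position - legitimate because the SCG is band-limited to 40 Hz and sampled
at 200 Hz.

Reference chaining is causal: the ICP reference is the ICP delay of the last
valid beat, the IRP reference the closest valid IRP among the 20 preceding
beats, with a two-beat look-ahead stability rule when no reference survives
(e.g. after an artifact run).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._extrema import local_maxima, local_minima
from ._timing import ms_to_samples, samples_to_ms
from .config import (AnchorConfig, FpConfig, HiresConfig, InflectionConfig,
                     PipelineConfig)
from .preprocess import BeatSegment

FP_LABELS = ("mc", "ao", "ac", "mo")


@dataclass
class AnchorPoint:
    """ICP or IRP anchor: delay from R, signed amplitude, prominence terms."""
    kind: str                    # "ICP" | "IRP"
    rdelay: float                # ms
    amplitude: float             # mg, signed (|amplitude| is |ICP_d| for ICP)
    idx: int                     # index into the beat's extended SCG window
    d1: Optional[float] = None   # mg, IRP only: drop to the adjacent left minimum
    d2: Optional[float] = None   # mg, IRP only: drop to the adjacent right minimum
    ref_rdelay: Optional[float] = None

    @property
    def d(self) -> Optional[float]:
        if self.d1 is None or self.d2 is None:
            return None
        return self.d1 + self.d2


@dataclass
class FiducialPoint:
    """One valve fiducial point with coarse (5 ms) and refined (1 ms) timing."""
    label: str                   # mc | ao | ac | mo
    cftp: float                  # ms, absolute, on the sample grid
    hrftp: Optional[float]       # ms, absolute, 1 ms grid (None if unrefined)
    r_time: float
    morphology: str              # peak | trough | inflection
    refined: bool = True

    @property
    def time(self) -> float:
        return self.cftp if self.hrftp is None else self.hrftp

    @property
    def rdelay(self) -> float:
        return self.time - self.r_time


# ---------------------------------------------------------------------------
# Anchor points

def find_icp(beat: BeatSegment, ref_rdelay: Optional[float] = None,
             cfg: Optional[AnchorConfig] = None) -> Optional[AnchorPoint]:
    """Deepest SCG minimum in S1si=[R+25, R+75] ms, within 30 ms of the reference.

    With no reference (record bootstrap, or after a gap) the deepest minimum
    is accepted unconditionally.
    """
    cfg = cfg or AnchorConfig()
    lo, hi = cfg.icp_window_ms
    a = beat.idx_at(beat.r_time + lo)
    b = beat.idx_at(beat.r_time + hi)
    mins = local_minima(beat.scg_ext)
    mins = mins[(mins >= a) & (mins <= b)]
    if ref_rdelay is not None:
        rd = beat.rdelay_of(mins) if mins.size else mins
        mins = mins[np.abs(np.asarray(rd) - ref_rdelay) <= cfg.icp_ref_tol_ms] \
            if mins.size else mins
    if mins.size == 0:
        return None
    vals = beat.scg_ext[mins]
    best = int(mins[int(np.argmin(vals))])     # deepest; argmin -> earliest on ties
    return AnchorPoint(kind="ICP", rdelay=beat.rdelay_of(best),
                       amplitude=float(beat.scg_ext[best]), idx=best,
                       ref_rdelay=ref_rdelay)


def _adjacent_min_value(x: np.ndarray, idx: int, side: int) -> float:
    """Value of the local minimum adjacent to ``idx`` (side=-1 left, +1 right).

    Falls back to the extreme value between ``idx`` and the array edge when
    no interior local minimum exists on that side.
    """
    mins = local_minima(x)
    if side < 0:
        cand = mins[mins < idx]
        if cand.size:
            return float(x[cand[-1]])
        return float(np.min(x[:idx + 1]))
    cand = mins[mins > idx]
    if cand.size:
        return float(x[cand[0]])
    return float(np.min(x[idx:]))


def irp_candidate(beat: BeatSegment, te_rdelay: float,
                  cfg: Optional[AnchorConfig] = None,
                  ref_rdelay: Optional[float] = None) -> Optional[AnchorPoint]:
    """Highest peak of S2si=[Te-30, Te+30] ms with prominence D=D1+D2 >= 7 mg.

    When ``ref_rdelay`` is given, only peaks within 20 ms of it compete; the
    returned anchor is the highest peak satisfying every active criterion.
    """
    cfg = cfg or AnchorConfig()
    a = beat.idx_at(beat.r_time + te_rdelay - cfg.s2si_half_ms)
    b = beat.idx_at(beat.r_time + te_rdelay + cfg.s2si_half_ms)
    a = max(a, 0)
    b = min(b, beat.scg_ext.size - 1)
    if b <= a:
        return None
    peaks = local_maxima(beat.scg_ext)
    peaks = peaks[(peaks >= a) & (peaks <= b)]
    if peaks.size == 0:
        return None
    order = peaks[np.argsort(-beat.scg_ext[peaks], kind="stable")]
    for p in order:
        p = int(p)
        rd = beat.rdelay_of(p)
        if ref_rdelay is not None and abs(rd - ref_rdelay) > cfg.irp_ref_tol_ms:
            continue
        v = float(beat.scg_ext[p])
        d1 = v - _adjacent_min_value(beat.scg_ext, p, -1)
        d2 = v - _adjacent_min_value(beat.scg_ext, p, +1)
        if d1 + d2 >= cfg.irp_d_min_mg:
            return AnchorPoint(kind="IRP", rdelay=rd, amplitude=v, idx=p,
                               d1=d1, d2=d2, ref_rdelay=ref_rdelay)
    return None


def find_irp(beat: BeatSegment, te_rdelay: Optional[float],
             history: Sequence[Tuple[int, float]] = (),
             lookahead: Sequence[Tuple[float, Optional[float]]] = (),
             cfg: Optional[AnchorConfig] = None) -> Optional[AnchorPoint]:
    """IRP anchor with reference congruency or two-beat look-ahead fallback.

    ``history``: ``(beat_index, irp_rdelay)`` of valid IRPs among the 20
    preceding beats, oldest first.  ``lookahead``: ``(rri, irp_rdelay)`` of
    the current beat followed by up to two subsequent beats, where the future
    delays come from :func:`irp_candidate` run without the reference rule.
    """
    cfg = cfg or AnchorConfig()
    if te_rdelay is None:
        return None
    if history:
        ref = history[-1][1]       # closest valid beat among the last 20
        return irp_candidate(beat, te_rdelay, cfg, ref_rdelay=ref)
    cand = irp_candidate(beat, te_rdelay, cfg, ref_rdelay=None)
    if cand is None:
        return None
    if len(lookahead) < 3:
        return None
    (rri_i, irp_i), (rri_1, irp_1), (rri_2, irp_2) = lookahead[:3]
    irp_i = cand.rdelay
    if irp_1 is None or irp_2 is None:
        return None
    ok = (abs(rri_i - rri_1) <= cfg.lookahead_rri_tol_ms
          and abs(irp_i - irp_1) <= cfg.lookahead_irp_tol_ms
          and abs(rri_1 - rri_2) <= cfg.lookahead_rri_tol_ms
          and abs(irp_1 - irp_2) <= cfg.lookahead_irp_tol_ms)
    return cand if ok else None


# ---------------------------------------------------------------------------
# Inflection detector

def _inflection_candidates(segment, dt_ms: float, polarity: str,
                           slope_frac: float, t0_ms: float) -> List[float]:
    """All qualifying shoulder times in a segment, left to right."""
    x = np.asarray(segment, dtype=float)
    if x.size < 4:
        return []
    d1 = np.diff(x)
    d2 = np.diff(x, 2)                       # d2[i] ~ curvature at sample i+1
    max_slope = np.max(np.abs(d1))
    if max_slope <= 0:
        return []
    sgn = 1.0 if polarity == "peak-like" else -1.0
    out = []
    for i in range(d2.size - 1):
        if sgn * d2[i] > 0 and sgn * d2[i + 1] < 0:
            # crossing between samples i+1 and i+2; slope there is d1[i+1]
            if abs(d1[i + 1]) < slope_frac * max_slope:
                frac = d2[i] / (d2[i] - d2[i + 1])
                out.append(t0_ms + (i + 1 + frac) * dt_ms)
    return out


def find_inflection(segment, dt_ms: float, polarity: str,
                    slope_frac: float = 0.3, t0_ms: float = 0.0) -> Optional[float]:
    """Shoulder locator: sign change of the second difference at low slope.

    ``polarity='peak-like'`` looks for a +to- change of the second difference
    (a smothered maximum), ``'trough-like'`` for -to+.  The first difference
    at the crossing must stay below ``slope_frac`` of the segment's maximum
    absolute slope.  Returns the leftmost qualifying time (linear
    interpolation of the zero crossing) or ``None``.
    """
    cands = _inflection_candidates(segment, dt_ms, polarity, slope_frac, t0_ms)
    return cands[0] if cands else None


# ---------------------------------------------------------------------------
# Sinc refinement

def _sinc_interp(x: np.ndarray, k0: int, t_ms: np.ndarray, fs: float) -> np.ndarray:
    """Whittaker-Shannon interpolation of ``x`` (101-sample window around k0)."""
    half = 50
    ks = np.arange(k0 - half, k0 + half + 1)
    window = x[ks[0]:ks[-1] + 1]
    # sinc passes exactly through the samples, so on-grid queries are exact
    arg = np.subtract.outer(np.asarray(t_ms) * fs / 1000.0, ks)
    return np.sinc(arg) @ window


def refine_hires(scg, cftp: float, extremum: str, fs: float,
                 cfg: Optional[HiresConfig] = None,
                 slope_frac: float = 0.3) -> Tuple[float, bool]:
    """Refine a coarse fiducial time to the 1 ms grid by sinc interpolation.

    ``scg`` is the full band-passed record (time origin at sample 0) and
    ``cftp`` the coarse time in ms on the sample grid.  A 101-sample window
    centred on the CFTP is interpolated and the extremum (or inflection)
    re-located on a 1 ms grid inside a 10 ms window centred on the CFTP.
    Returns ``(hrftp, refined)``; when the window is clipped by the record
    edge the CFTP is returned unrefined.
    """
    cfg = cfg or HiresConfig()
    x = np.asarray(scg, dtype=float)
    k0 = ms_to_samples(cftp, fs)
    half = (cfg.window_samples - 1) // 2
    if k0 - half < 0 or k0 + half >= x.size:
        return float(cftp), False
    span = cfg.halfspan_ms
    pad = 2.0 * cfg.grid_ms if extremum == "inflection" else 0.0
    t = np.arange(cftp - span - pad, cftp + span + pad + 0.5 * cfg.grid_ms,
                  cfg.grid_ms)
    y = _sinc_interp(x, k0, t, fs)
    if extremum in ("max", "min"):
        inner = (t >= cftp - span - 1e-9) & (t <= cftp + span + 1e-9)
        ti, yi = t[inner], y[inner]
        best = int(np.argmax(yi) if extremum == "max" else np.argmin(yi))
        return float(ti[best]), True
    if extremum == "inflection":
        # refine on the interpolated second difference, keeping the crossing
        # nearest the coarse estimate
        d2 = np.diff(y, 2)
        d1 = np.diff(y)
        max_slope = np.max(np.abs(d1)) or 1.0
        best_t, best_dist = None, np.inf
        for i in range(d2.size - 1):
            if d2[i] * d2[i + 1] < 0 and abs(d1[i + 1]) < slope_frac * max_slope:
                frac = d2[i] / (d2[i] - d2[i + 1])
                tc = t[0] + (i + 1 + frac) * cfg.grid_ms
                if abs(tc - cftp) <= span and abs(tc - cftp) < best_dist:
                    best_t, best_dist = tc, abs(tc - cftp)
        if best_t is None:
            return float(cftp), False
        return float(best_t), True
    raise ValueError(f"unknown extremum kind {extremum!r}")


# ---------------------------------------------------------------------------
# MC / AO and AC / MO rules

def _expected_window(history: Sequence[float], halfwidth: float
                     ) -> Optional[Tuple[float, float]]:
    if not history:
        return None
    m = float(np.mean(list(history)))
    return m - halfwidth, m + halfwidth


def _inflection_fallback(beat: BeatSegment, label: str, polarity: str,
                         history: Sequence[float], fs: float,
                         icfg: InflectionConfig, hcfg: HiresConfig,
                         scg_full: Optional[np.ndarray] = None
                         ) -> Optional[FiducialPoint]:
    """Look for a shoulder where the FP was expected from recent valid beats.

    Narrow shoulders are barely visible in a 5 ms second difference, so when
    the full record is available the expected window is first sinc-resampled
    to the hi-res (1 ms) grid and the inflection located there directly.
    """
    win = _expected_window(history, icfg.expected_halfwidth_ms)
    if win is None:
        return None
    centre = 0.5 * (win[0] + win[1])
    if scg_full is not None:
        k0 = ms_to_samples(beat.r_time + centre, fs)
        half = (hcfg.window_samples - 1) // 2
        if k0 - half >= 0 and k0 + half < len(scg_full):
            t_grid = np.arange(beat.r_time + win[0] - 2.0,
                               beat.r_time + win[1] + 2.0 + 0.5 * hcfg.grid_ms,
                               hcfg.grid_ms)
            y = _sinc_interp(np.asarray(scg_full, dtype=float), k0, t_grid, fs)
            cands = _inflection_candidates(y, hcfg.grid_ms, polarity,
                                           icfg.slope_frac, float(t_grid[0]))
            cands = [c for c in cands
                     if beat.r_time + win[0] <= c <= beat.r_time + win[1]]
            if not cands:
                return None
            # among qualifying shoulders, the one nearest the expected delay
            t = min(cands, key=lambda c: abs(c - (beat.r_time + centre)))
            cftp = samples_to_ms(ms_to_samples(t, fs), fs)
            return FiducialPoint(label=label, cftp=float(cftp), hrftp=float(t),
                                 r_time=beat.r_time, morphology="inflection",
                                 refined=True)
    lo = max(beat.idx_at(beat.r_time + win[0]) - 1, 0)
    hi = min(beat.idx_at(beat.r_time + win[1]) + 1, beat.scg_ext.size - 1)
    if hi - lo < 3:
        return None
    t = find_inflection(beat.scg_ext[lo:hi + 1], dt_ms=1000.0 / fs,
                        polarity=polarity, slope_frac=icfg.slope_frac,
                        t0_ms=beat.time_of(lo))
    if t is None:
        return None
    cftp = samples_to_ms(ms_to_samples(t, fs), fs)
    return FiducialPoint(label=label, cftp=float(cftp), hrftp=float(t),
                         r_time=beat.r_time, morphology="inflection",
                         refined=False)


def find_mc_ao(beat: BeatSegment, icp: AnchorPoint,
               cfg: Optional[FpConfig] = None,
               mc_history: Sequence[float] = (),
               ao_history: Sequence[float] = (),
               icfg: Optional[InflectionConfig] = None,
               hcfg: Optional[HiresConfig] = None,
               scg_full: Optional[np.ndarray] = None,
               s1si_ms: Optional[Tuple[float, float]] = None
               ) -> Tuple[Optional[FiducialPoint], Optional[FiducialPoint]]:
    """MC and AO from the ICP anchor.

    AO is the first peak after the ICP within 50 ms rising at least
    0.7*|ICP_d| above the ICP; MC is the symmetric first peak before it.
    Spurious low peaks near the anchor fail the amplitude rule and are
    skipped.  ``s1si_ms`` optionally confines candidate peaks to the S1
    search interval.  When no peak qualifies, the inflection fallback
    searches a +/-10 ms window around the mean delay of recent valid beats.
    """
    cfg = cfg or FpConfig()
    icfg = icfg or InflectionConfig()
    hcfg = hcfg or HiresConfig()
    dt = 1000.0 / beat.fs
    need = cfg.ao_amp_frac * abs(icp.amplitude)
    peaks = local_maxima(beat.scg_ext)
    if s1si_ms is not None:
        lo_i = beat.idx_at(beat.r_time + s1si_ms[0])
        hi_i = beat.idx_at(beat.r_time + s1si_ms[1])
        peaks = peaks[(peaks >= lo_i) & (peaks <= hi_i)]

    def _pick(after: bool) -> Optional[int]:
        window = cfg.ao_window_ms if after else cfg.mc_window_ms
        if after:
            cand = peaks[peaks > icp.idx]
        else:
            cand = peaks[peaks < icp.idx][::-1]      # scan backward in time
        for p in cand:
            gap = abs(int(p) - icp.idx) * dt
            if gap > window:
                break
            if beat.scg_ext[p] - icp.amplitude >= need:
                return int(p)
        return None

    out: List[Optional[FiducialPoint]] = []
    for label, after, hist in (("mc", False, mc_history), ("ao", True, ao_history)):
        p = _pick(after)
        if p is not None:
            cftp = beat.time_of(p)
            fp = FiducialPoint(label=label, cftp=cftp, hrftp=None,
                               r_time=beat.r_time, morphology="peak",
                               refined=False)
            if scg_full is not None:
                hr, refined = refine_hires(scg_full, cftp, "max", beat.fs, hcfg)
                fp.hrftp, fp.refined = hr, refined
            out.append(fp)
        else:
            out.append(_inflection_fallback(beat, label, "peak-like", hist,
                                            beat.fs, icfg, hcfg, scg_full))
    return out[0], out[1]


def find_ac_mo(beat: BeatSegment, irp: AnchorPoint,
               cfg: Optional[FpConfig] = None,
               ac_history: Sequence[float] = (),
               mo_history: Sequence[float] = (),
               icfg: Optional[InflectionConfig] = None,
               hcfg: Optional[HiresConfig] = None,
               scg_full: Optional[np.ndarray] = None
               ) -> Tuple[Optional[FiducialPoint], Optional[FiducialPoint]]:
    """AC and MO from the IRP anchor.

    AC is the first peak preceding the IRP with a 10-40 ms gap (closer peaks
    are skipped, farther ones end the scan); MO is the first trough following
    the IRP with a 10-30 ms gap.  Inflection fallback as for MC/AO.
    """
    cfg = cfg or FpConfig()
    icfg = icfg or InflectionConfig()
    hcfg = hcfg or HiresConfig()
    dt = 1000.0 / beat.fs
    peaks = local_maxima(beat.scg_ext)
    troughs = local_minima(beat.scg_ext)

    def _pick(cand, gap_lim) -> Optional[int]:
        lo, hi = gap_lim
        for p in cand:
            gap = abs(int(p) - irp.idx) * dt
            if gap < lo:
                continue
            if gap > hi:
                break
            return int(p)
        return None

    ac_idx = _pick(peaks[peaks < irp.idx][::-1], cfg.ac_gap_ms)
    mo_idx = _pick(troughs[troughs > irp.idx], cfg.mo_gap_ms)

    out: List[Optional[FiducialPoint]] = []
    for label, idx, morph, pol, hist in (
            ("ac", ac_idx, "peak", "peak-like", ac_history),
            ("mo", mo_idx, "trough", "trough-like", mo_history)):
        if idx is not None:
            cftp = beat.time_of(idx)
            fp = FiducialPoint(label=label, cftp=cftp, hrftp=None,
                               r_time=beat.r_time, morphology=morph,
                               refined=False)
            if scg_full is not None:
                kind = "max" if morph == "peak" else "min"
                hr, refined = refine_hires(scg_full, cftp, kind, beat.fs, hcfg)
                fp.hrftp, fp.refined = hr, refined
            out.append(fp)
        else:
            out.append(_inflection_fallback(beat, label, pol, hist,
                                            beat.fs, icfg, hcfg, scg_full))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Phase-2 orchestration over a beat sequence

def detect_fiducials(beats: List[BeatSegment], valid: Sequence[bool],
                     cfg: Optional[PipelineConfig] = None,
                     scg_full: Optional[np.ndarray] = None
                     ) -> List[Dict[str, object]]:
    """Run anchor + FP detection over screened beats with reference chaining.

    ``valid[i]`` marks beats that passed the artifact screen.  Returns one
    dict per beat with keys ``icp``, ``irp`` (anchors or None) and the four
    FP labels (FiducialPoint or None).  Deterministic: two passes over the
    same input give identical output.
    """
    cfg = cfg or PipelineConfig()
    n = len(beats)
    results: List[Dict[str, object]] = [
        {"icp": None, "irp": None, "mc": None, "ao": None, "ac": None, "mo": None}
        for _ in range(n)]
    icp_ref: Optional[float] = None
    irp_hist: List[Tuple[int, float]] = []          # (beat index, rdelay)
    fp_hist: Dict[str, List[float]] = {k: [] for k in FP_LABELS}
    la_cache: Dict[int, Optional[float]] = {}       # lookahead IRP candidates

    def lookahead_rdelay(j: int) -> Optional[float]:
        if j in la_cache:
            return la_cache[j]
        out = None
        if 0 <= j < n and valid[j] and beats[j].te_rdelay is not None:
            c = irp_candidate(beats[j], beats[j].te_rdelay, cfg.anchor)
            out = None if c is None else c.rdelay
        la_cache[j] = out
        return out

    for i, beat in enumerate(beats):
        if not valid[i]:
            continue
        res = results[i]
        # --- systolic side
        icp = find_icp(beat, icp_ref, cfg.anchor)
        res["icp"] = icp
        if icp is not None:
            icp_ref = icp.rdelay
            mc, ao = find_mc_ao(beat, icp, cfg.fp,
                                mc_history=fp_hist["mc"][-cfg.inflection.history_beats:],
                                ao_history=fp_hist["ao"][-cfg.inflection.history_beats:],
                                icfg=cfg.inflection, hcfg=cfg.hires,
                                scg_full=scg_full,
                                s1si_ms=(tuple(cfg.anchor.icp_window_ms)
                                         if cfg.fp.constrain_s1si else None))
            res["mc"], res["ao"] = mc, ao
        # --- diastolic side
        te = beat.te_rdelay
        if te is not None:
            hist = [(j, rd) for j, rd in irp_hist
                    if i - j <= cfg.anchor.irp_history_beats]
            la = [(beat.rri, None),
                  (beats[i + 1].rri if i + 1 < n else np.inf, lookahead_rdelay(i + 1)),
                  (beats[i + 2].rri if i + 2 < n else np.inf, lookahead_rdelay(i + 2))]
            irp = find_irp(beat, te, history=hist, lookahead=la, cfg=cfg.anchor)
            res["irp"] = irp
            if irp is not None:
                irp_hist.append((i, irp.rdelay))
                ac, mo = find_ac_mo(beat, irp, cfg.fp,
                                    ac_history=fp_hist["ac"][-cfg.inflection.history_beats:],
                                    mo_history=fp_hist["mo"][-cfg.inflection.history_beats:],
                                    icfg=cfg.inflection, hcfg=cfg.hires,
                                    scg_full=scg_full)
                res["ac"], res["mo"] = ac, mo
        for k in FP_LABELS:
            fp = res[k]
            if fp is not None:
                fp_hist[k].append(fp.rdelay)
    return results
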