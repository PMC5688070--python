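"""Per-beat artifact rejection.

Two stages, both stateless per beat:

1. *Gross gate* - a beat is a movement artifact when the band-passed SCG in
   the nominal beat window swings more than 50 mg peak-to-peak or has a
   variance above 28 mg^2.
2. *Morphology gate* - the SCG envelope (|scg| smoothed by a 31-tap
   triangular FIR) of a normal beat shows two heart-sound peaks, S1 and S2;
   the beat is kept only when S1 is taller than S2, S1 lies 10-160 ms after
   the R peak and S2 lies 300-480 ms after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal.windows import triang

from ._extrema import local_maxima
from .config import EnvelopeConfig, ScreenConfig
from .preprocess import BeatSegment


class DegenerateInputError(ValueError):
    """Input too short for the requested operation."""


@dataclass
class SoundPeak:
    """An S1 or S2 envelope peak: delay from R (ms) and envelope height (mg)."""
    rdelay: float
    amplitude: float


@dataclass
class EnvelopeResult:
    envelope: np.ndarray
    s1: Optional[SoundPeak] = None
    s2: Optional[SoundPeak] = None


@dataclass
class ScreenVerdict:
    status: str                       # valid | artifact_gross | artifact_morphology
    p2p: float = np.nan               # mg
    variance: float = np.nan          # mg^2
    failed_criteria: List[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return self.status == "valid"


def gross_gate(beat: BeatSegment, cfg: Optional[ScreenConfig] = None) -> ScreenVerdict:
    """Amplitude/variance gate on the nominal beat window (strict ``>``)."""
    cfg = cfg or ScreenConfig()
    x = np.asarray(beat.scg, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty beat")
    p2p = float(np.max(x) - np.min(x))
    var = float(np.var(x, ddof=0 if cfg.population_variance else 1))
    failed = []
    if p2p > cfg.p2p_mg:
        failed.append(f"p2p>{cfg.p2p_mg:g}mg")
    if var > cfg.var_mg2:
        failed.append(f"var>{cfg.var_mg2:g}mg2")
    status = "artifact_gross" if failed else "valid"
    return ScreenVerdict(status=status, p2p=p2p, variance=var, failed_criteria=failed)


def compute_envelope(scg, taps: int = 31) -> np.ndarray:
    """|scg| convolved with a unit-sum triangular kernel (same length).

    Unit-sum normalization keeps the envelope in milli-g so the S1/S2
    comparisons stay in physical units.
    """
    x = np.asarray(scg, dtype=float)
    if x.size < taps:
        raise DegenerateInputError(f"need at least {taps} samples, got {x.size}")
    kernel = triang(taps)
    kernel = kernel / kernel.sum()
    return np.convolve(np.abs(x), kernel, mode="same")


def locate_s1_s2(envelope: np.ndarray, beat: BeatSegment,
                 cfg: Optional[ScreenConfig] = None
                 ) -> Tuple[Optional[SoundPeak], Optional[SoundPeak]]:
    """Highest envelope local maxima in the S1 and S2 delay windows.

    ``envelope`` is the envelope of the beat's (extended) SCG window.  Ties
    between equal-height peaks are broken by the earlier one; a window with
    no local maximum yields ``None`` for that sound.
    """
    cfg = cfg or ScreenConfig()
    peaks = local_maxima(envelope)
    out = []
    for lo, hi in (cfg.s1_window_ms, cfg.s2_window_ms):
        a, b = beat.idx_at(beat.r_time + lo), beat.idx_at(beat.r_time + hi)
        cand = peaks[(peaks >= a) & (peaks <= b) & (peaks < envelope.size)]
        if cand.size == 0:
            out.append(None)
            continue
        best = cand[int(np.argmax(envelope[cand]))]  # argmax -> earliest on ties
        out.append(SoundPeak(rdelay=beat.rdelay_of(int(best)),
                             amplitude=float(envelope[best])))
    return out[0], out[1]


def morphology_gate(s1: Optional[SoundPeak], s2: Optional[SoundPeak],
                    cfg: Optional[ScreenConfig] = None) -> ScreenVerdict:
    """S1/S2 pattern check (applies only to beats that passed the gross gate)."""
    cfg = cfg or ScreenConfig()
    failed = []
    if s1 is None:
        failed.append("S1 absent")
    if s2 is None:
        failed.append("S2 absent")
    if s1 is not None and s2 is not None and not (s1.amplitude > s2.amplitude):
        failed.append("S1<=S2")
    if s1 is not None and not (cfg.s1_window_ms[0] <= s1.rdelay <= cfg.s1_window_ms[1]):
        failed.append("S1_Rdelay out of window")
    if s2 is not None and not (cfg.s2_window_ms[0] <= s2.rdelay <= cfg.s2_window_ms[1]):
        failed.append("S2_Rdelay out of window")
    status = "valid" if not failed else "artifact_morphology"
    return ScreenVerdict(status=status, failed_criteria=failed)


def screen_beat(beat: BeatSegment, screen_cfg: Optional[ScreenConfig] = None,
                env_cfg: Optional[EnvelopeConfig] = None
                ) -> Tuple[ScreenVerdict, Optional[EnvelopeResult]]:
    """Run both gates on one beat; returns the verdict and the envelope result."""
    screen_cfg = screen_cfg or ScreenConfig()
    env_cfg = env_cfg or EnvelopeConfig()
    verdict = gross_gate(beat, screen_cfg)
    if not verdict.is_valid:
        return verdict, None
    env = compute_envelope(beat.scg_ext, taps=env_cfg.taps)
    s1, s2 = locate_s1_s2(env, beat, screen_cfg)
    morph = morphology_gate(s1, s2, screen_cfg)
    morph.p2p, morph.variance = verdict.p2p, verdict.variance
    return morph, EnvelopeResult(envelope=env, s1=s1, s2=s2)
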