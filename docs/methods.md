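# Methods

## The problem

A seismocardiogram (SCG) is the few-milli-g precordial acceleration produced
by the beating heart, recorded here on the dorso-ventral axis together with
one ECG lead at a nominal 200 Hz.  Four SCG landmarks correspond to valve
events — mitral closure (MC), aortic opening (AO), aortic closure (AC) and
mitral opening (MO) — and from them the cardiac time intervals follow:

    PEP  = AO − Q          pre-ejection period
    ICT  = AO − MC         isovolumic contraction time
    LVET = AC − AO         left-ventricular ejection time
    IRT  = MO − AC         isovolumic relaxation time
    TEI  = (ICT + IRT) / LVET,   PEP/LVET,   LVET/RRI

Long sleep recordings combine tens of thousands of beats, heart rate swings
of 40–120 bpm, respiratory modulation of the waveform, and movement
artifacts 10–100× the signal amplitude, so the detector is built
precision-first: it prefers a missed beat over a wrong landmark.

## The three-phase procedure

**Phase 0 — conditioning.**  The SCG is band-passed 5–40 Hz with a
forward-reverse (zero-phase) Butterworth filter, 2nd order per pass.  Beats
are cut from 200 ms before each R peak to 200 ms before the next; R peaks
come from an annotation file or, as a fallback, a Pan-Tompkins-style energy
detector.  The first and last 0.5 s of the filtered record are excluded
(filter warm-up).  All millisecond thresholds are converted to samples with
round-half-away-from-zero in one central helper.

Because late diastole crosses the nominal beat boundary at high heart rate
(a 120-bpm beat ends 300 ms after its R peak, before the second heart sound
is over), each beat also exposes an *extended* window running to the next R
peak.  The extension contains no SCG activity of the following beat — its
systolic complex starts ≈25 ms after the next R — and is used only by the
envelope, T-end and diastolic searches.  Without it every beat near 120 bpm
would be structurally unanalyzable under the fixed 300–480 ms second-sound
window.

**Phase 1 — artifact screening.**  A beat is a gross artifact when the
band-passed SCG in the nominal window exceeds 50 mg peak-to-peak or 28 mg²
variance (population variance; strict `>`).  Surviving beats must show the
normal heart-sound envelope pattern: |SCG| smoothed by a unit-sum 31-tap
triangular FIR has an S1 peak 10–160 ms after R, an S2 peak 300–480 ms
after R, and S1 taller than S2.

**Phase 2 — fiducial points.**  Detection is anchored on the two clearest
SCG displacements.  The isovolumic contraction point (ICP) is the deepest
minimum of S1si = [R+25, R+75] ms within 30 ms of the last valid beat's ICP
delay (unconditional at bootstrap).  AO is the first peak after the ICP
within 50 ms rising at least 0.7·|ICP_d| above it (|ICP_d| = ICP distance
from 0 g); MC is the symmetric first peak before it.  The T-wave end (Te,
tangent method by default: steepest T-downslope tangent intersected with
the isoelectric baseline; trapezium-area method as alternative; plausible
band 150–500 ms) centres S2si = Te ± 30 ms.  The isovolumic relaxation
point (IRP) is the highest peak there whose prominence D = D1 + D2 against
the adjacent minima reaches 7 mg and whose delay is within 20 ms of the
closest valid IRP among the 20 preceding beats; with no usable history a
two-beat look-ahead is accepted instead when consecutive RR intervals agree
within 100 ms and IRP delays within 20 ms.  AC is the first peak 10–40 ms
before the IRP, MO the first trough 10–30 ms after it.

When the expected peak or trough degenerates into a *shoulder* (an
inflection of the waveform, seen in roughly 6% of beats), the inflection
stands in for the landmark: the expected window (±10 ms around the mean
delay of up to 5 recent valid beats) is sinc-resampled to 1 ms and the
+/− zero crossing of the second difference with first-difference magnitude
below 30% of the window's maximum slope is taken, choosing the qualifying
crossing nearest the expected delay.  (The stand-alone `find_inflection`
operator keeps the simpler leftmost-crossing contract.)  In noisy records a
flat shoulder usually carries small wiggle maxima that the amplitude rule
accepts within a few milliseconds of the true inflection, so the peak path
frequently serves shoulder beats too; the fallback matters for clean,
strictly monotone flanks.

Coarse positions (CFTP) live on the 5 ms sample grid and are refined to a
1 ms grid (HRFTP) by Whittaker–Shannon interpolation of a 101-sample window
centred on the CFTP, re-locating the feature inside a 10 ms window — valid
because the signal is band-limited to 40 Hz at fs = 200 Hz.  The wide
window suppresses truncation edge effects; no taper is applied.  A window
clipped by the record edge leaves the CFTP unrefined (flagged).

**Phase 3 — congruency checks and intervals.**  Each fiducial delay is
compared with its mean over the preceding 5 valid beats (the following 5
when no preceding value exists; partial windows of 1–5 values are allowed):
tolerance 10 ms for MC and AO, 20 ms for AC and MO.  The intervals are then
computed from the surviving refined delays and checked the same way (10 ms
for PEP, 20 ms for ICT/LVET/IRT); a violating interval is discarded
together with the fiducial points that produced it (an LVET violation drops
that beat's AO and AC), after which the beat's dependent intervals are
recomputed as missing.  Both checks are single-pass against the pre-removal
series, so results do not depend on processing order (an iterate-to-fixpoint
mode exists behind `congruency.iterate`).  Negative intervals are flagged
and set missing — they indicate mis-ordered landmarks.

## Key parameters

| parameter | default | unit | note |
|---|---|---|---|
| `filter.low_hz` / `high_hz` / `order` | 5 / 40 / 2 | Hz / – | zero-phase, order per pass |
| `screen.p2p_mg` / `var_mg2` | 50 / 28 | mg / mg² | gross artifact gates |
| `screen.s1_window_ms` / `s2_window_ms` | (10,160) / (300,480) | ms | envelope morphology |
| `envelope.taps` | 31 | samples | triangular FIR, unit sum |
| `anchor.icp_window_ms` | (25,75) | ms | S1si |
| `anchor.icp_ref_tol_ms` / `irp_ref_tol_ms` | 30 / 20 | ms | reference chaining |
| `anchor.irp_d_min_mg` | 7 | mg | IRP prominence D1+D2 |
| `fp.ao_amp_frac` | 0.7 | – | of ‖ICP_d‖, MC/AO amplitude rule |
| `fp.ac_gap_ms` / `mo_gap_ms` | (10,40) / (10,30) | ms | |
| `hires.window_samples` / `grid_ms` | 101 / 1 | – / ms | sinc refinement |
| `congruency.*_tol_ms` | 10 / 20 | ms | see above |

All thresholds sit in `PipelineConfig` and can be loaded from YAML; SCG
amplitudes are milli-g throughout because every amplitude threshold is
stated in mg.

## Synthetic recordings and what they do (not) show

The generator emulates the features the detector must survive, not cardiac
hemodynamics.  R times integrate a piecewise-linear commanded heart-rate
trajectory (40–120 bpm) plus 3% respiratory sinus arrhythmia.  Each beat's
SCG is a superposition of signed Gaussian bumps: a systolic complex
MC(+5 mg) – ICP(−12 mg) – AO(+8 mg) around R+45 ms with σ ≈ 6.5 ms, and a
diastolic complex AC(+5) – trough(−4.5) – IRP(+8) – MO(−5.5) tied to a
simulated T-end, Te ≈ 240 + 0.14·RRI ms, with the IRP 5 ms before Te.  The
intercept/slope keep Te in 310–450 ms over RRI 500–1500 ms, so the
second-sound envelope peak stays inside the fixed 300–480 ms morphology
window across the whole heart-rate span — the coherent way to make a
40–120 bpm sweep analyzable under fixed thresholds.  Respiration modulates
component amplitudes (±15% systolic, ±10% diastolic) and delays (±3 ms);
white delay jitter of 0.4 ms is added.  A configurable fraction of beats
(default 6%) renders MC as a shoulder: a sub-critical bump on the ICP
downstroke that produces a curvature zero crossing but no local maximum.
The rendered record is passed through a zero-phase order-6 45 Hz low-pass
so ≥95% of signal power lies in 5–40 Hz; band-limited 5–40 Hz noise of
0.3 mg RMS is then added.

Ground truth is read off the rendered noise-free waveform itself: each true
fiducial time is the extremum (or curvature zero crossing) of the
sinc-upsampled record near the bump centre, found on a 0.1 ms grid with
parabolic refinement.  Truth and signal therefore agree by construction,
and timing errors measured against it include every processing effect
except noise.

Movement artifacts are Tukey-windowed 15 Hz bursts of 60–1000 mg peak
(log-uniform) and 0.2–3 s duration, placed at random beats until the target
fraction of beats is corrupted.  The short (20 ms) amplitude tapers make
the truth flag crisp: a beat is flagged when the injected amplitude inside
its nominal window exceeds 30 mg, which guarantees a >50 mg injected
peak-to-peak swing for flagged beats and <60 mg spill for unflagged
neighbours.

What passing tests show: the detection logic, reference chaining,
refinement and filtering behave correctly on signals with the stated
morphology, rate dynamics, modulation and contamination.  What they do not
show: performance on real SCGs with inter-subject morphology differences,
posture changes, non-Gaussian waveshapes, arrhythmias, or ECG artifacts —
the empirical thresholds are known to need per-subject retuning in
practice, which is why every one of them is configuration.

## Numerical choices and degenerate inputs

* Sample↔ms conversion rounds half away from zero; 0-based sample k is at
  k·1000/fs ms.  Beat windows are contiguous on the sample grid.
* "Peak"/"trough" = strict local extremum; plateaus resolve to their
  leftmost sample; equal-height anchor candidates resolve to the earlier.
* The MC/AO search follows the 50 ms rule around the ICP; confining
  candidates to S1si additionally is available as `fp.constrain_s1si`
  (off by default — with a zero-phase filter the merged MC crest can drift
  a few ms before R+25 at low heart rate).
* Variance gate uses population variance (ddof = 0); a config flag selects
  sample variance.
* Te: the steepest-downslope search smooths the discrete derivative over
  25 ms first — without this, noise biases the tangent point steep and the
  T-end estimate ≈8 ms early.  Q is the last ECG local minimum in
  [R−80, R−8] ms; PEP is flagged low-confidence because Q comes from this
  heuristic rather than from annotations.
* Missing values propagate: no Te → no IRP → no AC/MO → those intervals
  missing; beats flagged artifact carry no fiducial or interval values.
* Fewer than 2 valid R peaks → empty output with a warning, never an abort.

## Limitations

* WFDB and EDF containers are not read by this build; inputs arrive as CSV
  (`t_ms,ecg,scg_z`) with annotation CSVs in ms or samples.
* The IRP look-ahead computes candidate anchors in the next two beats
  without their own reference check (avoiding infinite regress); the
  alternative — full recursion — is not implemented.
* The inflection detector is an operationalization (curvature sign change
  + slope-shoulder test); the phenomenon is morphological and no reference
  detector exists to compare against.
* Estimation rates and PPV reported by the tools are computed against
  synthetic ground truth with a ±10 ms matching tolerance standing in for
  a human audit of the waveform; the tolerance is configurable and reported
  alongside every PPV.
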