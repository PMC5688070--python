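"""Congruency filtering, cardiac time intervals, and the end-to-end pipeline.

Cardiac time intervals (CTIs) per beat, all from 1 ms-refined fiducial
delays:

* PEP  = AO - Q          (pre-ejection period)
* ICT  = AO - MC         (isovolumic contraction time)
* LVET = AC - AO         (left-ventricular ejection time)
* IRT  = MO - AC         (isovolumic relaxation time)
* PEP/LVET, TEI = (ICT + IRT)/LVET, LVET/RRI

Residual outliers are removed by two congruency checks: each fiducial delay
is compared with its average over the preceding 5 valid beats (or the
following 5 when no preceding value exists) with a 10 ms tolerance for MC
and AO and 20 ms for AC and MO; each CTI is checked the same way (10 ms for
PEP, 20 ms for the rest), and a violating CTI drags down the fiducial
points that produced it.  Both checks are single-pass against the pre-removal
series, so the outcome does not depend on processing order.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .artifact_screen import screen_beat
from .config import CongruencyConfig, PipelineConfig
from .fiducial_detect import FP_LABELS, detect_fiducials
from .preprocess import annotate_beats, bandpass_scg, segment_beats
from .record_io import BEAT_TABLE_COLUMNS, AnnotationStream, Record

log = logging.getLogger(__name__)

CTI_LABELS = ("pep", "ict", "lvet", "irt")

# fiducial points that enter each interval (Q is an ECG landmark, not an FP)
CTI_PARENTS = {"pep": ("ao",), "ict": ("mc", "ao"),
               "lvet": ("ao", "ac"), "irt": ("ac", "mo")}


def _reference_mean(values: np.ndarray, i: int, window: int) -> Optional[float]:
    """Mean over the nearest <=``window`` valid values before ``i``; else after."""
    prev = values[:i]
    prev = prev[~np.isnan(prev)]
    if prev.size:
        return float(np.mean(prev[-window:]))
    nxt = values[i + 1:]
    nxt = nxt[~np.isnan(nxt)]
    if nxt.size:
        return float(np.mean(nxt[:window]))
    return None


def fp_congruency_filter(fp_rdelays: pd.DataFrame,
                         cfg: Optional[CongruencyConfig] = None
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """First congruency check, per fiducial label independently.

    ``fp_rdelays``: columns mc/ao/ac/mo of refined delays (NaN = missing).
    Returns the filtered copy and a boolean drop mask.  Values are only ever
    removed, never altered; a constant series passes untouched.
    """
    cfg = cfg or CongruencyConfig()
    tol = {"mc": cfg.fp_tol_systolic_ms, "ao": cfg.fp_tol_systolic_ms,
           "ac": cfg.fp_tol_diastolic_ms, "mo": cfg.fp_tol_diastolic_ms}
    out = fp_rdelays.copy()
    dropped = pd.DataFrame(False, index=fp_rdelays.index, columns=list(FP_LABELS))
    while True:
        src = out.to_numpy(dtype=float)
        round_drops = 0
        for c, label in enumerate(FP_LABELS):
            col = src[:, c]
            for i in range(col.size):
                if np.isnan(col[i]):
                    continue
                ref = _reference_mean(col, i, cfg.window_beats)
                if ref is None:
                    continue
                if abs(col[i] - ref) > tol[label]:
                    out.iat[i, out.columns.get_loc(label)] = np.nan
                    dropped.iat[i, c] = True
                    round_drops += 1
        if not (cfg.iterate and round_drops):
            break
    return out, dropped


def compute_ctis(rri: float, q_rdelay: Optional[float],
                 fps: Dict[str, Optional[float]]) -> Tuple[Dict[str, float], List[str]]:
    """CTIs and derived ratios from one beat's fiducial delays (ms).

    Missing operands propagate to missing results; a negative interval marks
    the offending CTI missing and is flagged (it signals mis-ordered FPs).
    """
    mc, ao, ac, mo = (fps.get(k) for k in FP_LABELS)
    flags: List[str] = []

    def _diff(a, b, name):
        if a is None or b is None:
            return np.nan
        v = a - b
        if v <= 0:
            flags.append(f"negative:{name}")
            return np.nan
        return v

    pep = _diff(ao, q_rdelay, "pep")
    ict = _diff(ao, mc, "ict")
    lvet = _diff(ac, ao, "lvet")
    irt = _diff(mo, ac, "irt")
    out = {"pep": pep, "ict": ict, "lvet": lvet, "irt": irt,
           "pep_lvet": pep / lvet if not (np.isnan(pep) or np.isnan(lvet)) else np.nan,
           "tei": (ict + irt) / lvet
                  if not (np.isnan(ict) or np.isnan(irt) or np.isnan(lvet)) else np.nan,
           "lvet_rri": lvet / rri if not np.isnan(lvet) and rri > 0 else np.nan}
    return out, flags


def cti_congruency_filter(cti_df: pd.DataFrame, fp_rdelays: pd.DataFrame,
                          q_rdelays: np.ndarray, rris: np.ndarray,
                          cfg: Optional[CongruencyConfig] = None
                          ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Second congruency check, on the CTIs.

    A CTI farther than its tolerance from the 5-beat reference mean is
    discarded together with the fiducial points that produced it (an LVET
    violation drops that beat's AO and AC), and the beat's CTIs are then
    recomputed from the surviving points - so dependent intervals go missing
    too.  Single pass against the pre-removal series.
    """
    cfg = cfg or CongruencyConfig()
    tol = {"pep": cfg.cti_tol_pep_ms, "ict": cfg.cti_tol_other_ms,
           "lvet": cfg.cti_tol_other_ms, "irt": cfg.cti_tol_other_ms}
    n = len(cti_df)
    fp_out = fp_rdelays.copy()
    flags = pd.DataFrame("", index=cti_df.index, columns=["cti_flags"])
    drop_fp = pd.DataFrame(False, index=cti_df.index, columns=list(FP_LABELS))
    for label in CTI_LABELS:
        col = cti_df[label].to_numpy(dtype=float)
        for i in range(n):
            if np.isnan(col[i]):
                continue
            ref = _reference_mean(col, i, cfg.window_beats)
            if ref is None:
                continue
            if abs(col[i] - ref) > tol[label]:
                for parent in CTI_PARENTS[label]:
                    drop_fp.loc[i, parent] = True
                flags.loc[i, "cti_flags"] = (flags.loc[i, "cti_flags"] +
                                             f"cti_congruency:{label};")
    for label in FP_LABELS:
        fp_out.loc[drop_fp[label], label] = np.nan
    # recompute CTIs for affected beats from the surviving fiducial points
    cti_out = cti_df.copy()
    affected = drop_fp.any(axis=1)
    for i in np.nonzero(affected.to_numpy())[0]:
        fps = {k: (None if np.isnan(fp_out.iloc[i][k]) else float(fp_out.iloc[i][k]))
               for k in FP_LABELS}
        q = q_rdelays[i] if not np.isnan(q_rdelays[i]) else None
        vals, _ = compute_ctis(rris[i], q, fps)
        for k, v in vals.items():
            cti_out.iloc[i, cti_out.columns.get_loc(k)] = v
    return cti_out, fp_out, flags


# ---------------------------------------------------------------------------
# End-to-end pipeline

def run_pipeline(record: Record, annotations: AnnotationStream,
                 cfg: Optional[PipelineConfig] = None
                 ) -> Tuple[pd.DataFrame, dict]:
    """Band-pass -> segment -> artifact screen -> fiducial points -> CTIs.

    Never aborts on per-beat failures; each beat row carries its status and
    rejection provenance.  Deterministic: identical inputs and configuration
    yield an identical beat table.
    """
    cfg = cfg or PipelineConfig()
    scg_f = bandpass_scg(record.scg, record.fs, cfg.filter.low_hz,
                         cfg.filter.high_hz, cfg.filter.order)
    beats = segment_beats(record, annotations, scg_filtered=scg_f,
                          edge_guard_s=cfg.edge_guard_s)
    n = len(beats)
    verdicts = []
    for b in beats:
        v, _ = screen_beat(b, cfg.screen, cfg.envelope)
        verdicts.append(v)
    valid = [v.is_valid for v in verdicts]
    annotate_beats(beats, cfg)
    fid = detect_fiducials(beats, valid, cfg, scg_full=scg_f)

    fp_rdelays = pd.DataFrame(
        {k: [fid[i][k].rdelay if fid[i][k] is not None else np.nan
             for i in range(n)] for k in FP_LABELS})
    fp_filtered, fp_dropped = fp_congruency_filter(fp_rdelays, cfg.congruency)

    q_rdelays = np.array([b.q_rdelay if b.q_rdelay is not None else np.nan
                          for b in beats])
    rris = np.array([b.rri for b in beats])
    cti_rows = []
    for i in range(n):
        fps = {k: (None if np.isnan(fp_filtered.iloc[i][k])
                   else float(fp_filtered.iloc[i][k])) for k in FP_LABELS}
        q = None if np.isnan(q_rdelays[i]) else float(q_rdelays[i])
        vals, fl = compute_ctis(rris[i], q, fps)
        vals["_flags"] = ";".join(fl)
        cti_rows.append(vals)
    cti_df = pd.DataFrame(cti_rows)
    neg_flags = cti_df.pop("_flags")
    cti_df2, fp_final, cti_flags = cti_congruency_filter(
        cti_df, fp_filtered, q_rdelays, rris, cfg.congruency)

    rows = []
    for i, b in enumerate(beats):
        v = verdicts[i]
        row = {
            "beat": i, "r_ms": b.r_time, "rri_ms": b.rri,
            "status": v.status,
            "failed_criteria": ";".join(v.failed_criteria),
            "q_rdelay_ms": q_rdelays[i] if v.is_valid else np.nan,
            "te_rdelay_ms": (b.te_rdelay if v.is_valid and b.te_rdelay is not None
                             else np.nan),
        }
        for k in FP_LABELS:
            fp = fid[i][k]
            present = fp is not None and not np.isnan(fp_final.iloc[i][k])
            row[f"{k}_cftp_ms"] = fp.cftp - b.r_time if present else np.nan
            row[f"{k}_hrftp_ms"] = (fp.hrftp - b.r_time
                                    if present and fp.hrftp is not None else np.nan)
            row[f"{k}_rdelay_ms"] = fp_final.iloc[i][k] if present else np.nan
            morph = fp.morphology if present else ""
            if fp is not None and not present:
                morph = ("congruency_dropped" if (fp_dropped.iloc[i][k]
                                                  or np.isnan(fp_final.iloc[i][k]))
                         else morph)
            row[f"{k}_morph"] = morph
        for k in ("pep", "ict", "lvet", "irt", "pep_lvet", "tei", "lvet_rri"):
            suffix = "_ms" if k in CTI_LABELS else ""
            row[f"{k}{suffix}"] = cti_df2.iloc[i][k] if v.is_valid else np.nan
        row["pep_lowconf"] = int(v.is_valid and not np.isnan(q_rdelays[i]))
        row["cti_flags"] = ((neg_flags.iloc[i] + ";" if neg_flags.iloc[i] else "")
                            + cti_flags.iloc[i]["cti_flags"]) if v.is_valid else ""
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(BEAT_TABLE_COLUMNS))

    n_free = int(sum(valid))
    summary = {
        "n_beats": n,
        "n_artifact_free": n_free,
        "pct_artifact_free": 100.0 * n_free / n if n else np.nan,
        "n_artifact_gross": int(sum(v.status == "artifact_gross" for v in verdicts)),
        "n_artifact_morphology": int(sum(v.status == "artifact_morphology"
                                         for v in verdicts)),
    }
    got_all = np.ones(n, dtype=bool)
    for k in FP_LABELS:
        got = (~table[f"{k}_rdelay_ms"].isna()).to_numpy()
        got_all &= got
        summary[f"rate_{k}_pct"] = (100.0 * got[valid].sum() / n_free
                                    if n_free else np.nan)
    summary["rate_all4_pct"] = (100.0 * got_all[valid].sum() / n_free
                                if n_free else np.nan)
    summary["n_all4"] = int(got_all[valid].sum())
    return table, summary
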