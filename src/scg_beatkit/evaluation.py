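"""Scoring detections against ground truth.

A detection is a true positive when it falls within the matching tolerance
(default 10 ms) of the true fiducial time of the same beat; otherwise it is
a false positive (and the unmatched truth a false negative).  Precision is
summarized as the positive predictive value, PPV = TPos / (TPos + FPos).
Tolerance-based matching stands in for a human audit of the waveforms and is
reported alongside every PPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .record_io import FP_LABELS, IndexingError


@dataclass
class LabelCounts:
    tpos: int = 0
    fpos: int = 0
    fneg: int = 0
    errors: list = field(default_factory=list)    # ms, matched pairs only


@dataclass
class MatchResult:
    tolerance_ms: float
    labels: Dict[str, LabelCounts] = field(default_factory=dict)

    def all_errors(self) -> np.ndarray:
        out = []
        for c in self.labels.values():
            out.extend(c.errors)
        return np.asarray(out, dtype=float)


@dataclass
class QualityReport:
    pct_artifact_free: float
    fp_rates_pct: Dict[str, float]
    all_four_rate_pct: float
    n_beats: int
    n_artifact_free: int


def _align(truth: pd.DataFrame, detected: pd.DataFrame,
           tol_ms: float = 1.0) -> pd.DataFrame:
    """Pair truth and detection rows by nearest R time (within ``tol_ms``)."""
    tr = truth["r_ms"].to_numpy(dtype=float)
    dr = detected["r_ms"].to_numpy(dtype=float)
    idx = np.searchsorted(tr, dr)
    idx = np.clip(idx, 0, tr.size - 1)
    left = np.clip(idx - 1, 0, tr.size - 1)
    nearest = np.where(np.abs(tr[left] - dr) < np.abs(tr[idx] - dr), left, idx)
    bad = np.abs(tr[nearest] - dr) > tol_ms
    if bad.any():
        raise IndexingError(
            f"{int(bad.sum())} detected beat(s) have no matching R time "
            f"in the truth table")
    t = truth.iloc[nearest].reset_index(drop=True)
    d = detected.reset_index(drop=True)
    t.columns = [f"{c}_true" if c in d.columns else c for c in t.columns]
    d.columns = [f"{c}_det" if f"{c}_true" in t.columns else c for c in d.columns]
    return pd.concat([t, d], axis=1)


def match_detections(truth: pd.DataFrame, detected: pd.DataFrame,
                     tolerance_ms: float = 10.0) -> MatchResult:
    """Per-label TPos/FPos/FNeg counts and timing errors.

    Truth rows flagged ``artifact`` contribute no false negatives, but any
    detection inside them counts as a false positive.
    """
    m = _align(truth, detected)
    res = MatchResult(tolerance_ms=tolerance_ms)
    for label in FP_LABELS:
        c = LabelCounts()
        true_t = m[f"{label}_ms"].to_numpy(dtype=float)
        det_rd = m[f"{label}_rdelay_ms"].to_numpy(dtype=float)
        r = m["r_ms_true"].to_numpy(dtype=float)
        art = m["artifact"].to_numpy() == 1
        det_t = r + det_rd
        for i in range(len(m)):
            has_det = not np.isnan(det_rd[i])
            has_true = not np.isnan(true_t[i])
            if art[i]:
                if has_det:
                    c.fpos += 1
                continue
            if has_det and has_true:
                err = det_t[i] - true_t[i]
                if abs(err) <= tolerance_ms:
                    c.tpos += 1
                    c.errors.append(float(err))
                else:
                    c.fpos += 1
                    c.fneg += 1
            elif has_det:
                c.fpos += 1
            elif has_true:
                c.fneg += 1
        res.labels[label] = c
    return res


def compute_ppv(match: MatchResult) -> Dict[str, Optional[float]]:
    """PPV per label in [0, 1]; ``None`` (with a warning) when undetermined."""
    import logging
    out: Dict[str, Optional[float]] = {}
    for label, c in match.labels.items():
        denom = c.tpos + c.fpos
        if denom == 0:
            logging.getLogger(__name__).warning("no detections for %s: PPV undefined",
                                                label)
            out[label] = None
        else:
            out[label] = c.tpos / denom
    return out


def quality_report(beat_table: pd.DataFrame) -> QualityReport:
    """Signal quality and per-FP estimation rates from a beat table.

    Estimation rates are percentages of the artifact-free beats, so the
    all-four rate can never exceed any single-point rate.
    """
    n = len(beat_table)
    valid = (beat_table["status"] == "valid").to_numpy()
    n_free = int(valid.sum())
    rates = {}
    got_all = np.ones(n, dtype=bool)
    for label in FP_LABELS:
        got = (~beat_table[f"{label}_rdelay_ms"].isna()).to_numpy()
        got_all &= got
        rates[label] = 100.0 * got[valid].sum() / n_free if n_free else np.nan
    return QualityReport(
        pct_artifact_free=100.0 * n_free / n if n else np.nan,
        fp_rates_pct=rates,
        all_four_rate_pct=100.0 * got_all[valid].sum() / n_free if n_free else np.nan,
        n_beats=n, n_artifact_free=n_free)


def sample_for_audit(detections: pd.DataFrame, frac: float = 0.10,
                     seed: int = 0) -> pd.DataFrame:
    """Reproducible uniform sample (without replacement) of the valid beats.

    Supports the manual-audit workflow on real data, where an operator
    reviews ~10% of the valid beats against a reference template.
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    valid = detections[detections["status"] == "valid"]
    k = int(round(frac * len(valid)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(valid.index.to_numpy(), size=k, replace=False))
    return valid.loc[idx]
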