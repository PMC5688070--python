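"""Record and annotation I/O.

On-disk contract
----------------
* Record CSV: header ``t_ms,ecg,scg_z``; ECG in arbitrary units, SCG in
  milli-g (dorso-ventral axis), one row per sample, uniform sampling.
* Annotation CSV: header ``r_ms`` (or ``r_sample`` plus a sampling rate),
  optional ``valid`` column of 0/1 flags.
* Ground-truth / beat tables: delimited text with one row per beat, missing
  values as empty fields, numeric fields written to 3 decimals (beat table)
  or full precision (truth table).

WFDB and EDF containers are not supported by this build; requesting them
raises :class:`UnsupportedFormatError`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed or incomplete input file."""


class UnsupportedFormatError(ValueError):
    """Container format not handled by this build."""


class ValidationError(ValueError):
    """Input violates a stream invariant (e.g. non-monotone R times)."""


class IndexingError(ValueError):
    """Two tables that must share beat indexing do not align."""


@dataclass
class Record:
    """Synchronized two-channel physiological record (ECG + dorso-ventral SCG)."""

    ecg: np.ndarray
    scg: np.ndarray            # milli-g
    fs: float                  # Hz
    start_time: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.scg = np.asarray(self.scg, dtype=float)
        if self.ecg.shape != self.scg.shape or self.ecg.ndim != 1:
            raise ValidationError("ecg and scg must be 1-D arrays of equal length")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.ecg.size

    @property
    def duration_ms(self) -> float:
        return self.n * 1000.0 / self.fs


@dataclass
class AnnotationStream:
    """Ordered R-peak times in ms from record start, with per-R validity flags."""

    r_ms: np.ndarray
    validity: np.ndarray = None
    source: str = "file"       # "file" | "detector"

    def __post_init__(self):
        self.r_ms = np.asarray(self.r_ms, dtype=float)
        if self.validity is None:
            self.validity = np.ones(self.r_ms.size, dtype=bool)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.validity.shape != self.r_ms.shape:
            raise ValidationError("validity flags must match r_ms length")
        if self.r_ms.size > 1 and not np.all(np.diff(self.r_ms) > 0):
            bad = np.nonzero(np.diff(self.r_ms) <= 0)[0] + 1
            raise ValidationError(f"R-peak times not strictly increasing at indices {bad.tolist()}")

    @property
    def valid_r_ms(self) -> np.ndarray:
        return self.r_ms[self.validity]


# ---------------------------------------------------------------------------
# Records

RECORD_COLUMNS = ("t_ms", "ecg", "scg_z")


def read_record(path, format: str = "csv", fs: Optional[float] = None) -> Record:
    """Read a two-channel record.  Only ``format='csv'`` is supported."""
    if format in ("wfdb", "edf"):
        raise UnsupportedFormatError(
            f"{format!r} containers are not supported by this build; convert to CSV "
            f"({','.join(RECORD_COLUMNS)})"
        )
    if format != "csv":
        raise UnsupportedFormatError(f"unknown record format {format!r}")
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot parse record CSV {path}: {e}") from None
    missing = [c for c in ("ecg", "scg_z") if c not in df.columns]
    if missing:
        raise FormatError(f"record CSV {path} missing channel column(s): {missing}")
    if df.shape[0] == 0:
        raise FormatError(f"record CSV {path} contains no samples")
    if "t_ms" in df.columns:
        t = df["t_ms"].to_numpy(dtype=float)
        if t.size > 1:
            dt = np.diff(t)
            med = float(np.median(dt))
            if med <= 0 or np.any(np.abs(dt - med) > 0.01 * med):
                raise UnsupportedFormatError(f"non-uniform sampling in {path}")
            fs_inferred = 1000.0 / med
        elif fs is None:
            raise FormatError(f"single-sample record {path} needs an explicit fs")
        else:
            fs_inferred = fs
        if fs is not None and abs(fs - fs_inferred) > 0.01 * fs:
            raise FormatError(f"declared fs={fs} disagrees with t_ms spacing ({fs_inferred:.3f})")
        fs = fs_inferred
    elif fs is None:
        raise FormatError(f"record CSV {path} has no t_ms column and no fs was given")
    scale = 1.0  # CSV contract: scg_z already in milli-g; header scale hook for other units
    return Record(ecg=df["ecg"].to_numpy(dtype=float),
                  scg=df["scg_z"].to_numpy(dtype=float) * scale,
                  fs=float(fs))


def write_record(record: Record, path) -> None:
    """Write a record as full-precision CSV (round trips bit-exactly)."""
    t = np.arange(record.n) * 1000.0 / record.fs
    arr = np.column_stack([t, record.ecg, record.scg])
    np.savetxt(path, arr, fmt="%.17g", delimiter=",",
               header=",".join(RECORD_COLUMNS), comments="")


# ---------------------------------------------------------------------------
# Annotations

def read_annotations(path, fs: Optional[float] = None) -> AnnotationStream:
    """Read R-peak annotations (``r_ms`` column, or ``r_sample`` + ``fs``).

    Adjacent duplicate times are collapsed with a logged warning; decreasing
    times raise :class:`ValidationError` listing the offending indices.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"annotation file {path} is empty") from None
    if "r_ms" in df.columns:
        t = df["r_ms"].to_numpy(dtype=float)
    elif "r_sample" in df.columns:
        if fs is None:
            raise FormatError("r_sample annotations require a sampling rate")
        t = df["r_sample"].to_numpy(dtype=float) * 1000.0 / fs
    else:
        raise FormatError(f"annotation file {path} has neither r_ms nor r_sample column")
    valid = (df["valid"].to_numpy(dtype=bool) if "valid" in df.columns
             else np.ones(t.size, dtype=bool))
    dec = np.nonzero(np.diff(t) < 0)[0] + 1
    if dec.size:
        raise ValidationError(f"annotation times decrease at indices {dec.tolist()}")
    keep = np.ones(t.size, dtype=bool)
    keep[1:] = np.diff(t) > 0
    if not keep.all():
        log.warning("collapsed %d duplicate R-peak annotation(s)", int((~keep).sum()))
    return AnnotationStream(r_ms=t[keep], validity=valid[keep], source="file")


def write_annotations(stream: AnnotationStream, path) -> None:
    pd.DataFrame({"r_ms": stream.r_ms,
                  "valid": stream.validity.astype(int)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ground-truth and beat tables (plain DataFrames with a fixed schema)

TRUTH_COLUMNS = ["r_ms", "rri_ms", "q_ms", "te_ms", "icp_ms", "irp_ms",
                 "mc_ms", "ao_ms", "ac_ms", "mo_ms", "artifact", "mc_morph"]

FP_LABELS = ("mc", "ao", "ac", "mo")

BEAT_TABLE_COLUMNS = (
    ["beat", "r_ms", "rri_ms", "status", "failed_criteria",
     "q_rdelay_ms", "te_rdelay_ms"]
    + [f"{fp}_{suffix}" for fp in FP_LABELS
       for suffix in ("cftp_ms", "hrftp_ms", "rdelay_ms", "morph")]
    + ["pep_ms", "ict_ms", "lvet_ms", "irt_ms",
       "pep_lvet", "tei", "lvet_rri", "pep_lowconf", "cti_flags"]
)

_NUMERIC_BEAT_COLS = [c for c in BEAT_TABLE_COLUMNS
                      if c.endswith(("_ms",)) or c in ("pep_lvet", "tei", "lvet_rri")]


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, float_format="%.6f")


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"truth table {path} missing columns {missing}")
    return df


def write_beat_table(table: pd.DataFrame, path) -> None:
    """Write a per-beat output table (3-decimal floats, empty for missing)."""
    missing = [c for c in BEAT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"beat table schema incomplete, missing {missing}")
    out = table[list(BEAT_TABLE_COLUMNS)].copy()
    try:
        out.to_csv(path, index=False, float_format="%.3f")
    except OSError as e:
        raise OSError(f"cannot write beat table to {path}: {e}") from None


def read_beat_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEAT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"beat table {path} missing columns {missing}")
    return df
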