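"""Centralized time <-> sample index conversion.

All internal timing is milliseconds from record start; sample k of a record
sampled at ``fs`` Hz lies at ``k * 1000 / fs`` ms.  Millisecond thresholds are
converted to sample counts with round-half-away-from-zero so that the same
rule applies symmetrically to pre-R (negative) and post-R offsets.
"""

from __future__ import annotations

import numpy as np


def ms_to_samples(t_ms, fs: float):
    """Convert time in ms to the nearest sample index (ties away from zero)."""
    x = np.asarray(t_ms, dtype=float) * float(fs) / 1000.0
    out = np.trunc(x + np.copysign(0.5, x)).astype(np.int64)
    if np.isscalar(t_ms) or np.ndim(t_ms) == 0:
        return int(out)
    return out


def samples_to_ms(k, fs: float):
    """Time of sample index ``k`` in ms from record start."""
    out = np.asarray(k, dtype=float) * 1000.0 / float(fs)
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(out)
    return out
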