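"""Strict local extremum search with leftmost-plateau resolution.

A "peak" is a sample strictly greater than the nearest distinct values on
both sides; plateaus contribute their leftmost sample.  Array endpoints are
never extrema (their outer neighbour is unknown).
"""

from __future__ import annotations

import numpy as np


def local_maxima(x) -> np.ndarray:
    """Indices of strict local maxima of ``x`` (plateau -> leftmost sample)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            # scan across a possible plateau
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=np.int64)


def local_minima(x) -> np.ndarray:
    """Indices of strict local minima of ``x`` (plateau -> leftmost sample)."""
    return local_maxima(-np.asarray(x, dtype=float))
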