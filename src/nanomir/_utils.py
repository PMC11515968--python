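"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def geomean(values, zero_replace: float | None = 1.0) -> float:
    """Geometric mean of nonnegative values.

    Zeros are replaced by ``zero_replace`` (default 1, so log2(1)=0 enters the
    mean) before the log transform; pass ``zero_replace=None`` to propagate a
    zero result instead.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("geomean of empty collection")
    if np.any(v < 0):
        raise ValueError("geomean requires nonnegative values")
    if zero_replace is not None:
        v = np.where(v == 0, zero_replace, v)
    elif np.any(v == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


def log2p(x, pseudocount: float = 1.0):
    """log2(x + pseudocount), the log transform used for all count statistics."""
    return np.log2(np.asarray(x, dtype=float) + pseudocount)
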