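"""Numerical kernel for batched local-similarity scoring.

Because every run of the local-similarity dynamic program keeps a constant
index offset (each DP step moves (i-1, j-1) -> (i, j)), the score for one
delay d reduces to a nonnegative-clipped maximal contiguous-subarray sum of
the aligned products x[i] * y[i+d].  The batched kernel exploits this to
score thousands of permuted series quickly; it is JIT-compiled with numba
when available, with an equivalent vectorized numpy fallback.
"""

from __future__ import annotations

import numpy as np

__all__ = ["batch_max_ls", "HAVE_NUMBA"]


def _batch_max_ls_py(x: np.ndarray, Y: np.ndarray, max_delay: int) -> np.ndarray:
    """Vectorized fallback: raw (unnormalized) max LS per row of Y."""
    m, n = Y.shape
    best = np.zeros(m)
    for d in range(-max_delay, max_delay + 1):
        i0, i1 = max(0, -d), min(n, n - d)
        s = x[i0:i1] * Y[:, i0 + d : i1 + d]
        pos = np.zeros(m)
        neg = np.zeros(m)
        for k in range(s.shape[1]):
            pos = np.maximum(0.0, pos + s[:, k])
            neg = np.maximum(0.0, neg - s[:, k])
            np.maximum(best, pos, out=best)
            np.maximum(best, neg, out=best)
    return best


try:
    from numba import njit

    @njit(cache=True)
    def _batch_max_ls_nb(x, Y, max_delay):  # pragma: no cover - numba
        m, n = Y.shape
        out = np.zeros(m)
        for r in range(m):
            best = 0.0
            for d in range(-max_delay, max_delay + 1):
                i0 = -d if d < 0 else 0
                i1 = n - d if d > 0 else n
                pos = 0.0
                neg = 0.0
                for i in range(i0, i1):
                    s = x[i] * Y[r, i + d]
                    pos = pos + s
                    if pos < 0.0:
                        pos = 0.0
                    neg = neg - s
                    if neg < 0.0:
                        neg = 0.0
                    if pos > best:
                        best = pos
                    if neg > best:
                        best = neg
            out[r] = best
        return out

    HAVE_NUMBA = True

    def batch_max_ls(x: np.ndarray, Y: np.ndarray, max_delay: int) -> np.ndarray:
        return _batch_max_ls_nb(
            np.ascontiguousarray(x, dtype=np.float64),
            np.ascontiguousarray(Y, dtype=np.float64),
            int(max_delay),
        )

except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
    batch_max_ls = _batch_max_ls_py
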