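"""Compiled inner loops for the row-action sweeps.

The sweep is inherently sequential (each row update reads the result of the
previous one), so it is written as a tight scalar loop over the CSR arrays
and compiled with numba.  ``nogil=True`` lets independent block sweeps of
the parallel-block solver run on real threads.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(nogil=True, cache=False)
def sweep_rows(indptr, indices, data, row_norm2, b, x, lam, row_lo, row_hi, clamp_each_step):
    """One relaxed-projection pass over rows [row_lo, row_hi) in place.

    For each row a^i: x <- x + lam * (b_i - a^i . x) / ||a^i||^2 * a^i,
    optionally clamping the touched entries of x to be non-negative after
    every row (only touched entries can have turned negative).  Rows with
    zero norm are skipped.
    """
    for r in range(row_lo, row_hi):
        lo, hi = indptr[r], indptr[r + 1]
        nrm = row_norm2[r]
        if nrm <= 0.0:
            continue
        dot = 0.0
        for k in range(lo, hi):
            dot += data[k] * x[indices[k]]
        coef = lam * (b[r] - dot) / nrm
        if clamp_each_step:
            for k in range(lo, hi):
                j = indices[k]
                v = x[j] + coef * data[k]
                x[j] = v if v > 0.0 else 0.0
        else:
            for k in range(lo, hi):
                x[indices[k]] += coef * data[k]
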