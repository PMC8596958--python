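"""JIT-compiled recurrent loop for the LSTM backward pass.

The forward pass is transcendental-bound and runs fastest through NumPy's
vectorized ufuncs; the backward recurrence is multiply-bound and benefits
from loop fusion, so it is compiled here when numba is available. The kernel
implements exactly the same arithmetic as the NumPy reference loop in
``rnn.py`` (gate layout [input, forget, output | candidate]); equivalence is
asserted in the test suite. Without numba the reference loop is used.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def bwd_loop(SIG, G, TC, CP, Wh, dH):  # pragma: no cover - compiled
    M, T, B, h3 = SIG.shape
    h = h3 // 3
    h2 = 2 * h
    DA = np.empty((M, T, B, 4 * h), dtype=SIG.dtype)
    dh0 = np.empty((M, h), dtype=SIG.dtype)
    dc0 = np.empty((M, h), dtype=SIG.dtype)
    for m in range(M):
        dh_next = np.zeros((B, h), dtype=SIG.dtype)
        dc_next = np.zeros((B, h), dtype=SIG.dtype)
        for t in range(T - 1, -1, -1):
            da = DA[m, t]
            for b in range(B):
                for j in range(h):
                    si = SIG[m, t, b, j]
                    sf = SIG[m, t, b, j + h]
                    so = SIG[m, t, b, j + h2]
                    g = G[m, t, b, j]
                    tc = TC[m, t, b, j]
                    cp = CP[m, t, b, j]
                    dh = dH[m, t, b, j] + dh_next[b, j]
                    dc = dc_next[b, j] + dh * so * (1.0 - tc * tc)
                    da[b, j] = dc * g * si * (1.0 - si)
                    da[b, j + h] = dc * cp * sf * (1.0 - sf)
                    da[b, j + h2] = dh * tc * so * (1.0 - so)
                    da[b, j + h3] = dc * si * (1.0 - g * g)
                    dc_next[b, j] = dc * sf
            dh_next = np.dot(da, Wh[m])
        for j in range(h):
            sh = 0.0
            sc = 0.0
            for b in range(B):
                sh += dh_next[b, j]
                sc += dc_next[b, j]
            dh0[m, j] = sh
            dc0[m, j] = sc
    return DA, dh0, dc0
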