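"""Numerical kernels for 1D local regression.

The jitted kernel evaluates a tricube-weighted local polynomial at sorted
evaluation points against sorted training data, using centered and
range-normalized local coordinates ``t = (x - x0) / dmax`` so the local
normal equations are well conditioned. A slow pure-python twin with
identical semantics backs it when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _eval_sorted_1d(xs, ys, xe, q, degree, dmax_scale):
    """Evaluate local fits at sorted points ``xe`` given sorted training
    ``xs, ys``; window size ``q``; ``dmax_scale >= 1`` inflates the
    tricube radius (span > 1 semantics). Returns (values, n_fallback)
    where n_fallback counts rank-deficient windows that fell back to a
    lower degree or the window mean.
    """
    n = xs.shape[0]
    ne = xe.shape[0]
    out = np.empty(ne)
    n_fallback = 0
    s = 0
    for i in range(ne):
        x0 = xe[i]
        while s + q < n and xs[s + q] - x0 < x0 - xs[s]:
            s += 1
        dmax = max(x0 - xs[s], xs[s + q - 1] - x0)
        if dmax <= 0.0:
            # all window points coincide with x0: plain window mean
            acc = 0.0
            for j in range(s, s + q):
                acc += ys[j]
            out[i] = acc / q
            continue
        dmax = dmax * dmax_scale
        # accumulate tricube-weighted moments in t = (x - x0)/dmax
        S0 = 0.0; S1 = 0.0; S2 = 0.0; S3 = 0.0; S4 = 0.0
        T0 = 0.0; T1 = 0.0; T2 = 0.0
        for j in range(s, s + q):
            t = (xs[j] - x0) / dmax
            a = abs(t)
            if a >= 1.0:
                continue  # boundary/tied points carry zero tricube weight
            w = 1.0 - a * a * a
            w = w * w * w
            wy = w * ys[j]
            S0 += w
            T0 += wy
            wt = w * t
            S1 += wt
            T1 += wy * t
            wt2 = wt * t
            S2 += wt2
            T2 += wy * t * t
            S3 += wt2 * t
            S4 += wt2 * t * t
        if S0 <= 0.0:
            # every window point sits exactly at the tricube boundary
            acc = 0.0
            for j in range(s, s + q):
                acc += ys[j]
            out[i] = acc / q
            n_fallback += 1
            continue
        done = False
        if degree == 2:
            det = (S0 * (S2 * S4 - S3 * S3)
                   - S1 * (S1 * S4 - S2 * S3)
                   + S2 * (S1 * S3 - S2 * S2))
            if abs(det) > 1e-12 * S0 * S0 * S0:
                out[i] = (T0 * (S2 * S4 - S3 * S3)
                          - S1 * (T1 * S4 - S3 * T2)
                          + S2 * (T1 * S3 - S2 * T2)) / det
                done = True
            else:
                n_fallback += 1
        if not done:
            det2 = S0 * S2 - S1 * S1
            if degree >= 1 and abs(det2) > 1e-12 * S0 * S0:
                out[i] = (T0 * S2 - T1 * S1) / det2
            else:
                if degree == 1:
                    n_fallback += 1
                out[i] = T0 / S0  # local tricube-weighted mean
    return out, n_fallback


def eval_sorted_1d(xs, ys, xe, q, degree, dmax_scale=1.0):
    """Dispatch to the jitted kernel (or its python twin)."""
    return _eval_sorted_1d(
        np.ascontiguousarray(xs, dtype=np.float64),
        np.ascontiguousarray(ys, dtype=np.float64),
        np.ascontiguousarray(xe, dtype=np.float64),
        int(q),
        int(degree),
        float(dmax_scale),
    )
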