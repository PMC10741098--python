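"""Independent brute-force oracles used across the test suite.

These deliberately share no code with the package internals: local
regression is recomputed per evaluation point with explicit neighbor
selection and a weighted least-squares solve via ``numpy.linalg.lstsq``;
t and F distribution functions are obtained by numerical integration of
hand-written densities.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


# ---------------------------------------------------------------------------
# brute-force LOESS
# ---------------------------------------------------------------------------

def tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.abs(u) ** 3) ** 3
    w[np.abs(u) >= 1.0] = 0.0
    return w


def loess_oracle_1d(x, y, x_eval, span=0.75, degree=2):
    """Per-point tricube weighted polynomial fit via lstsq."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = min(n, math.ceil(span * n))
    scale = 1.0 if span <= 1.0 else span
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, float)):
        d = np.abs(x - x0)
        dq = np.sort(d)[q - 1]
        if dq == 0.0:
            out[i] = y[d == 0.0].mean()
            continue
        dmax = dq * scale
        sel = d <= dq
        w = tricube(d[sel] / dmax)
        dx = x[sel] - x0
        A = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], y[sel] * sw, rcond=None)
        out[i] = beta[0]
    return out


def trimmed_sd_oracle(col, trim=0.05):
    n = len(col)
    k = int(math.floor(trim * n))
    core = np.sort(col)[k: n - k] if n - 2 * k >= 2 else np.sort(col)
    return core.std()


def loess_oracle_2d(X, y, X_eval, span=0.75, degree=2):
    """Two-predictor analogue: Euclidean distance on trimmed-SD scaled
    columns, full local quadratic with the cross term."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    q = min(n, math.ceil(span * n))
    scales = np.array([trimmed_sd_oracle(X[:, j]) for j in range(2)])
    Xs = X / scales
    out = np.empty(len(X_eval))
    for i, p in enumerate(np.asarray(X_eval, float) / scales):
        d = np.sqrt(((Xs - p) ** 2).sum(axis=1))
        dq = np.sort(d)[q - 1]
        if dq == 0.0:
            out[i] = y[d == 0.0].mean()
            continue
        sel = d <= dq
        w = tricube(d[sel] / dq)
        u = Xs[sel, 0] - p[0]
        v = Xs[sel, 1] - p[1]
        if degree == 2:
            A = np.column_stack([np.ones(u.size), u, v, u * u, u * v, v * v])
        else:
            A = np.column_stack([np.ones(u.size), u, v])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], y[sel] * sw, rcond=None)
        out[i] = beta[0]
    return out


# ---------------------------------------------------------------------------
# distribution-function oracles by numerical integration
# ---------------------------------------------------------------------------

def t_pdf(x, df):
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_sf_oracle(x, df):
    """P(T >= x) by adaptive quadrature of the density."""
    if x < 0:
        return 1.0 - t_sf_oracle(-x, df)
    val, _ = quad(t_pdf, x, np.inf, args=(df,))
    return val


def f_pdf(x, d1, d2):
    if x <= 0:
        return 0.0
    logc = (math.lgamma((d1 + d2) / 2) - math.lgamma(d1 / 2)
            - math.lgamma(d2 / 2) + (d1 / 2) * math.log(d1 / d2))
    logpdf = logc + (d1 / 2 - 1) * math.log(x) - ((d1 + d2) / 2) * math.log1p(d1 * x / d2)
    return math.exp(logpdf)


def f_cdf_oracle(x, d1, d2):
    val, _ = quad(f_pdf, 0, x, args=(d1, d2), limit=200)
    return min(1.0, val)


def welch_t_oracle(a, b):
    """Welch two-sided t-test p-value from first principles (statistic,
    Welch-Satterthwaite df, numerically integrated t tail)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2.0 * t_sf_oracle(abs(t), df)


def f_test_oracle(a, b):
    """Two-sided variance-ratio test p-value via the integrated F CDF."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    f = a.var(ddof=1) / b.var(ddof=1)
    cdf = f_cdf_oracle(f, len(a) - 1, len(b) - 1)
    return f, min(1.0, 2.0 * min(cdf, 1.0 - cdf))
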