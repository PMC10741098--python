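"""Locally weighted polynomial regression (LOESS) from first principles.

This mirrors the classic Cleveland procedure as R's ``loess`` applies it
with default settings (span 0.75, local quadratic, tricube weights, no
robustness iterations), with one deliberate dialect difference: every
point is fit *directly* — there is no interpolation surface over a
k-d-tree partition — so values can differ from R's interpolated output
at roughly the 1e-3 level while being exactly reproducible by a
brute-force per-point weighted-least-squares oracle.

For each evaluation point ``x0`` the ``q = ceil(span * n)`` nearest
training points (absolute distance in 1D; Euclidean distance on
trimmed-SD-normalized columns in 2D) are weighted by the tricube
``w = (1 - (d / d_max)^3)^3`` and a polynomial of the requested degree is
fit by weighted least squares; the local prediction is its value at
``x0``. Points tied with the q-th distance are included with zero weight,
so window-boundary ties never affect the fit. Spans above 1 inflate the
tricube radius by ``span ** (1 / n_predictors)`` (the R convention), which
makes the degree-1 fit converge to the global least-squares line as the
span grows.

The estimator is scikit-learn compatible (``get_params``/``set_params``,
trailing-underscore fitted attributes) so it composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._loess_kernel import eval_sorted_1d
from .errors import ExtrapolationError, InputError, SpanTooSmallError

__all__ = ["LoessFit", "LoessRegressor", "loess_fit", "loess_predict"]

logger = logging.getLogger(__name__)


def _as_matrix(x) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] not in (1, 2):
        raise InputError("predictors must form an (n,) vector or an (n, 1|2) matrix")
    return X


def _trimmed_sd(col: np.ndarray, trim: float = 0.05) -> float:
    """SD after dropping a fraction ``trim`` from each tail (10% total),
    approximating the predictor normalization R's loess applies."""
    n = col.size
    k = int(math.floor(trim * n))
    core = np.sort(col)[k: n - k] if n - 2 * k >= 2 else np.sort(col)
    return float(core.std())


def _poly_terms(dx: np.ndarray, degree: int) -> np.ndarray:
    """Local design matrix columns (without intercept) for centered
    predictors ``dx`` of shape (m, p)."""
    cols = [dx[:, j] for j in range(dx.shape[1])]
    if degree == 2:
        for j in range(dx.shape[1]):
            for k in range(j, dx.shape[1]):
                cols.append(dx[:, j] * dx[:, k])
    return np.column_stack(cols)


class LoessRegressor(RegressorMixin, BaseEstimator):
    """LOESS smoother with 1 or 2 predictors.

    Parameters
    ----------
    span : fraction of the data in each local window, in (0, 1]; values
        above 1 keep the full window and inflate the tricube radius.
    degree : local polynomial degree, 1 or 2 (2 matches R's default).
    extrapolation : ``"error"`` (default) raises when predicting outside
        the training range; ``"clamp"`` clips to the range with a warning.

    Attributes (after :meth:`fit`)
    ------------------------------
    fitted_values_ : local predictions at the training points.
    residuals_ : ``y - fitted_values_`` (exact elementwise).
    r_squared_ : ``1 - SS_res / SS_tot`` (defined as 1.0 for constant y).
    n_fallback_ : number of evaluation points where a rank-deficient
        local design fell back to a lower degree or the window mean.
    """

    def __init__(self, span: float = 0.75, degree: int = 2,
                 extrapolation: str = "error"):
        self.span = span
        self.degree = degree
        self.extrapolation = extrapolation

    # -- validation ----------------------------------------------------
    def _check_params(self, n: int, p: int) -> int:
        if not (0.0 < self.span):
            raise SpanTooSmallError("span must be positive")
        if self.degree not in (1, 2):
            raise InputError("degree must be 1 or 2")
        if self.extrapolation not in ("error", "clamp"):
            raise InputError("extrapolation must be 'error' or 'clamp'")
        q = min(n, int(math.ceil(self.span * n)))
        n_terms = 1 + p * self.degree + (p * (p - 1) // 2 if self.degree == 2 else 0)
        if q < max(self.degree + 2, n_terms + 1):
            raise SpanTooSmallError(
                f"window of {q} points cannot support a degree-{self.degree} "
                f"local fit in {p} predictor(s); increase span"
            )
        return q

    # -- fitting -------------------------------------------------------
    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise InputError("x and y lengths differ")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise InputError("non-finite values in predictors or response")
        n, p = X.shape
        q = self._check_params(n, p)
        self.X_, self.y_, self.q_ = X, y, q
        if p == 2:
            scales = np.array([_trimmed_sd(X[:, j]) for j in range(2)])
            keep = scales > 0.0
            self._scales_ = scales
            self._keep_cols_ = keep
            if keep.sum() == 0:
                self._effective_p_ = 0
            elif keep.sum() == 1:
                self._effective_p_ = 1  # degenerate column dropped; 1D path
            else:
                self._effective_p_ = 2
        else:
            sd = float(X[:, 0].std())
            self._keep_cols_ = np.array([sd > 0.0])
            self._effective_p_ = 1 if sd > 0 else 0
            self._scales_ = np.array([1.0])
        self.fitted_values_, self.n_fallback_ = self._evaluate(X)
        if self.n_fallback_:
            logger.warning(
                "loess: %d rank-deficient local design(s); fell back to a "
                "lower-degree/weighted-mean local fit", self.n_fallback_,
            )
        self.residuals_ = y - self.fitted_values_
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((self.residuals_ ** 2).sum())
        self.r_squared_ = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        return self

    # -- evaluation core ----------------------------------------------
    def _evaluate(self, X_new: np.ndarray) -> tuple[np.ndarray, int]:
        if self._effective_p_ == 0:
            return np.full(X_new.shape[0], self.y_.mean()), 0
        if self._effective_p_ == 1:
            col = int(np.flatnonzero(self._keep_cols_)[0])
            return self._evaluate_1d(self.X_[:, col], X_new[:, col])
        return self._evaluate_2d(X_new)

    def _evaluate_1d(self, x: np.ndarray, xe: np.ndarray) -> tuple[np.ndarray, int]:
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], self.y_[order]
        eorder = np.argsort(xe, kind="stable")
        scale = 1.0 if self.span <= 1.0 else self.span ** (1.0 / 1.0)
        vals_sorted, n_fb = eval_sorted_1d(xs, ys, xe[eorder], self.q_,
                                           self.degree, scale)
        out = np.empty_like(vals_sorted)
        out[eorder] = vals_sorted
        return out, n_fb

    def _evaluate_2d(self, X_new: np.ndarray) -> tuple[np.ndarray, int]:
        Xs = self.X_ / self._scales_
        Xe = X_new / self._scales_
        y = self.y_
        q = self.q_
        radius_scale = 1.0 if self.span <= 1.0 else self.span ** 0.5
        out = np.empty(Xe.shape[0])
        n_fb = 0
        n_terms = {1: 3, 2: 6}[self.degree]
        for i in range(Xe.shape[0]):
            d = np.hypot(Xs[:, 0] - Xe[i, 0], Xs[:, 1] - Xe[i, 1])
            dq = np.partition(d, q - 1)[q - 1]
            if dq <= 0.0:
                out[i] = y[d <= 0.0].mean()
                continue
            dmax = dq * radius_scale
            idx = np.flatnonzero(d <= dq)  # ties included (zero weight)
            u = d[idx] / dmax
            w = (1.0 - u ** 3) ** 3
            w[u >= 1.0] = 0.0
            wsum = w.sum()
            if wsum <= 0.0:
                out[i] = y[idx].mean()
                n_fb += 1
                continue
            dx = Xs[idx] - Xe[i]
            A = np.column_stack([np.ones(idx.size), _poly_terms(dx, self.degree)])
            sw = np.sqrt(w)
            beta, _, rank, _ = np.linalg.lstsq(A * sw[:, None], y[idx] * sw,
                                               rcond=None)
            if rank < n_terms:
                n_fb += 1
                out[i] = float(np.dot(w, y[idx]) / wsum)
            else:
                out[i] = beta[0]
        return out, n_fb

    # -- prediction ----------------------------------------------------
    def predict(self, X):
        if not hasattr(self, "fitted_values_"):
            raise InputError("regressor is not fitted")
        X_new = _as_matrix(X)
        if X_new.shape[1] != self.X_.shape[1]:
            raise InputError("prediction predictors have wrong width")
        lo, hi = self.X_.min(axis=0), self.X_.max(axis=0)
        below, above = X_new < lo, X_new > hi
        if below.any() or above.any():
            if self.extrapolation == "error":
                raise ExtrapolationError(
                    "prediction point(s) outside the training predictor range"
                )
            logger.warning("loess: clamping %d out-of-range prediction point(s)",
                           int((below | above).any(axis=1).sum()))
            X_new = np.clip(X_new, lo, hi)
        values, _ = self._evaluate(X_new)
        return values


@dataclass
class LoessFit:
    """Frozen result of a LOESS fit (predictors, response, span, degree,
    per-point fitted values, residuals and R^2)."""

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    fitted: np.ndarray
    residual: np.ndarray
    r_squared: float
    n_fallback: int
    regressor: LoessRegressor

    def to_frame(self):
        """Serializable view (x columns, y, fitted, residual)."""
        import pandas as pd

        d = {f"x{j}": self.x[:, j] for j in range(self.x.shape[1])}
        d.update(y=self.y, fitted=self.fitted, residual=self.residual)
        return pd.DataFrame(d)


def loess_fit(x, y, span: float = 0.75, degree: int = 2,
              extrapolation: str = "error") -> LoessFit:
    """Fit a LOESS smoother and return the populated :class:`LoessFit`."""
    reg = LoessRegressor(span=span, degree=degree,
                         extrapolation=extrapolation).fit(x, y)
    return LoessFit(
        x=reg.X_, y=reg.y_, span=span, degree=degree,
        fitted=reg.fitted_values_, residual=reg.residuals_,
        r_squared=reg.r_squared_, n_fallback=reg.n_fallback_, regressor=reg,
    )


def loess_predict(fit: LoessFit, x_new) -> np.ndarray:
    """Evaluate the same local-fit procedure at new points (within the
    training range; behavior outside is governed by the fit's
    ``extrapolation`` setting)."""
    return fit.regressor.predict(x_new)
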