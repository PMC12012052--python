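"""Locally weighted regression (LOESS) with tricube weights.

Self-contained so its behaviour is testable against explicit weighted
normal equations, rather than delegating to a plotting layer. At each
evaluation point the ``ceil(span * n)`` nearest observations (ties broken by
lower index) are fit with a weighted polynomial of the requested degree,
weights ``w = (1 - (d / d_max)^3)^3``.

Pointwise standard errors come from the local hat vector ``l(x0)`` and a
global residual variance estimate: ``se(x0) = sigma * ||l(x0)||`` with
``sigma^2 = RSS / (n - tr(L))`` computed from the fit at the data points.
No robustness iterations are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class LoessFit:
    """A LOESS curve evaluated on a grid, with pointwise standard errors."""

    eval_x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float
    degree: int
    n_points: int

    @property
    def ci_low(self) -> np.ndarray:
        return self.fitted - 1.96 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.fitted + 1.96 * self.se


def _local_solve(x: np.ndarray, y: np.ndarray, x0: float, k: int, degree: int):
    """Weighted polynomial fit at x0; returns (fitted value, hat vector)."""
    n = x.size
    d = np.abs(x - x0)
    # argsort is stable, so distance ties resolve to the lower index
    idx = np.argsort(d, kind="stable")[:k]
    d_max = d[idx].max()
    if d_max == 0:
        w_local = np.ones(k)
    else:
        w_local = (1.0 - (d[idx] / d_max) ** 3) ** 3
    w_local = np.clip(w_local, 0.0, None)
    if w_local.sum() <= 0:
        w_local = np.ones(k)
    # design matrix centred at x0: fitted value is the intercept
    X = np.vander(x[idx] - x0, N=degree + 1, increasing=True)
    W = w_local
    XtW = X.T * W
    A = XtW @ X
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
    # hat vector over the local points: e0^T (X^T W X)^-1 X^T W
    l_local = Ainv[0] @ XtW
    l_full = np.zeros(n)
    l_full[idx] = l_local
    return float(l_full @ y), l_full


class LoessRegression(BaseEstimator, RegressorMixin):
    """LOESS smoother with tricube weights and local polynomial fits.

    Parameters
    ----------
    span : float in (0, 1]
        Fraction of observations entering each local fit.
    degree : {1, 2}
        Local polynomial degree.

    Attributes
    ----------
    x_ : ndarray of shape (n,)
        Training predictor, as given.
    y_ : ndarray of shape (n,)
        Training response.
    sigma2_ : float
        Global residual variance estimate, RSS / (n - tr(L)).
    trace_hat_ : float
        Trace of the smoother matrix over the training points.
    """

    def __init__(self, span: float = 0.75, degree: int = 1):
        self.span = span
        self.degree = degree

    def _validate(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if not (0 < self.span <= 1):
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {self.degree}")
        if np.unique(x).size < self.degree + 2:
            raise ValueError(
                f"need at least degree + 2 = {self.degree + 2} distinct x values"
            )
        k = int(np.ceil(self.span * x.size))
        if k < self.degree + 2:
            raise ValueError(
                f"span {self.span} with n = {x.size} gives {k} local points; "
                f"need at least degree + 2 = {self.degree + 2}"
            )
        return x, y, k

    def fit(self, X, y):
        """Store the data and estimate the global residual variance.

        ``X`` may be 1-D or a single-column 2-D array.
        """
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("LoessRegression is univariate; X must have one column")
            x = x[:, 0]
        x, y, k = self._validate(x, y)
        self.x_ = x
        self.y_ = y
        self.k_ = k
        # smoother diagonal + residuals at the data points
        fitted = np.empty(x.size)
        trace = 0.0
        for i, xi in enumerate(x):
            fi, l_full = _local_solve(x, y, xi, k, self.degree)
            fitted[i] = fi
            trace += l_full[i]
        resid = y - fitted
        dof = max(x.size - trace, 1.0)
        self.fitted_train_ = fitted
        self.trace_hat_ = trace
        self.sigma2_ = float(resid @ resid) / dof
        return self

    def predict(self, X, return_se: bool = False):
        """Evaluate the smoother. Extrapolation outside the data range is an error."""
        check_is_fitted(self, "x_")
        x0s = np.asarray(X, dtype=float)
        if x0s.ndim == 2:
            x0s = x0s[:, 0]
        x0s = x0s.ravel()
        lo, hi = self.x_.min(), self.x_.max()
        if (x0s < lo).any() or (x0s > hi).any():
            raise ValueError(
                f"evaluation points outside the data range [{lo}, {hi}]; "
                "no extrapolation"
            )
        fitted = np.empty(x0s.size)
        se = np.empty(x0s.size)
        for j, x0 in enumerate(x0s):
            fj, l_full = _local_solve(self.x_, self.y_, x0, self.k_, self.degree)
            fitted[j] = fj
            se[j] = np.sqrt(self.sigma2_ * float(l_full @ l_full))
        if return_se:
            return fitted, se
        return fitted

    def curve(self, eval_x=None, num: int = 100) -> LoessFit:
        """Evaluate on a grid (default: uniform over the data range)."""
        check_is_fitted(self, "x_")
        if eval_x is None:
            eval_x = np.linspace(self.x_.min(), self.x_.max(), num)
        eval_x = np.asarray(eval_x, dtype=float).ravel()
        fitted, se = self.predict(eval_x, return_se=True)
        return LoessFit(
            eval_x=eval_x, fitted=fitted, se=se,
            span=self.span, degree=self.degree, n_points=int(self.x_.size),
        )


def loess_fit(x, y, span: float = 0.75, degree: int = 1, eval_x=None) -> LoessFit:
    """Functional wrapper: fit a :class:`LoessRegression` and evaluate it."""
    model = LoessRegression(span=span, degree=degree).fit(np.asarray(x), np.asarray(y))
    return model.curve(eval_x)
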