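"""Socio-economic disparity curves and the accessibility/car-ownership turning point.

Deprivation curves smooth a sector-level air-pollution metric (annual mean or
summer/winter ratio) against the deprivation decile (1 = most deprived,
treated as numeric), separately per degree-of-urbanisation class.

The turning-point analysis operationalises "the score beyond which car
ownership starts to drop": a LOESS fit of cars per household against the
accessibility score is differentiated on a fine grid, and the turning point
is the smallest score at which the derivative falls below a negative
threshold (default half the largest descent rate) and stays below it for the
rest of the range. A curve that is already descending at that rate from the
start of the range has no regime change and yields ``detected_ = False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .local_regression import LoessFit, LoessRegression

logger = logging.getLogger(__name__)


@dataclass
class DisparityCurve:
    """LOESS curve of one exposure metric vs deprivation decile in one DEGURBA class."""

    metric: str
    degurba_class: int
    curve: LoessFit
    n_sectors: int


def deprivation_curves(
    metrics: pd.DataFrame,
    sectors: pd.DataFrame,
    span: float = 0.75,
    degree: int = 1,
    min_sectors: int = 5,
    eval_points: int = 40,
) -> list[DisparityCurve]:
    """Smooth each metric against the deprivation decile per DEGURBA class.

    ``metrics`` has a ``sector_id`` column plus one column per metric;
    ``sectors`` carries ``sector_id``, ``degurba`` and ``bimd_decile``.
    Strata with fewer than ``min_sectors`` sectors are skipped with a warning.
    """
    merged = metrics.merge(
        sectors[["sector_id", "degurba", "bimd_decile"]], on="sector_id"
    ).dropna(subset=["bimd_decile"])
    metric_cols = [c for c in metrics.columns if c != "sector_id"]
    curves: list[DisparityCurve] = []
    for metric in metric_cols:
        for deg in sorted(merged["degurba"].unique()):
            block = merged[merged["degurba"] == deg].dropna(subset=[metric])
            if len(block) < min_sectors:
                logger.warning(
                    "DEGURBA class %s has %d sectors for %s (< %d); skipped",
                    deg, len(block), metric, min_sectors,
                )
                continue
            x = block["bimd_decile"].to_numpy(dtype=float)
            y = block[metric].to_numpy(dtype=float)
            if np.unique(x).size < 3:
                logger.warning("too few distinct deciles in DEGURBA %s; skipped", deg)
                continue
            model = LoessRegression(span=span, degree=degree).fit(x, y)
            eval_x = np.linspace(x.min(), x.max(), eval_points)
            curves.append(
                DisparityCurve(
                    metric=metric,
                    degurba_class=int(deg),
                    curve=model.curve(eval_x),
                    n_sectors=len(block),
                )
            )
    return curves


def curves_to_frame(curves: list[DisparityCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for x, f, lo, hi in zip(c.curve.eval_x, c.curve.fitted, c.curve.ci_low, c.curve.ci_high):
            rows.append((c.metric, c.degurba_class, x, f, lo, hi, c.n_sectors))
    return pd.DataFrame(
        rows, columns=["metric", "degurba", "decile", "fitted", "ci_low", "ci_high", "n_sectors"]
    )


class TurningPointDetector(BaseEstimator):
    """Detect the score at which a smoothed curve starts a sustained decline.

    Fits a LOESS curve of ``y`` (cars per household) against ``X`` (the
    accessibility score), differentiates it on a fine grid, and reports the
    smallest score at which the derivative drops below
    ``threshold_frac * max|derivative|`` (a negative threshold) and remains
    below it to the end of the range.

    Two refinements keep the rule stable where car ownership saturates or the
    changepoint sits near the range edge: the detection window ends once the
    smoothed curve has completed ``1 - tail_tol`` of its total decline
    (ownership cannot fall below zero, so the curve flattens at the floor and
    its derivative there carries no regime information), and the derivative is
    averaged over ``deriv_smooth`` grid points before thresholding to damp
    smoothing wiggle.

    Parameters
    ----------
    span : float
        LOESS span; small enough to resolve a changepoint near the range edge.
    degree : {1, 2}
        Local polynomial degree.
    threshold_frac : float in (0, 1)
        Fraction of the maximum descent rate defining "rapid decline".
    grid_points : int
        Size of the fine evaluation grid.
    tail_tol : float in (0, 1)
        Fraction of the total decline treated as "already completed" when
        closing the detection window.
    deriv_smooth : odd int
        Moving-average width (grid points) applied to the derivative.

    Attributes
    ----------
    detected_ : bool
    x_star_ : float or nan
        The turning point (score units) when detected.
    pre_slope_, post_slope_ : float
        Straight-line slopes fit on either side of ``x_star_``.
    curve_ : LoessFit
        The smoothed curve on the fine grid.
    """

    def __init__(
        self,
        span: float = 0.15,
        degree: int = 1,
        threshold_frac: float = 0.5,
        grid_points: int = 401,
        tail_tol: float = 0.1,
        deriv_smooth: int = 9,
    ):
        self.span = span
        self.degree = degree
        self.threshold_frac = threshold_frac
        self.grid_points = grid_points
        self.tail_tol = tail_tol
        self.deriv_smooth = deriv_smooth

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        x = x.ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 30:
            raise ValueError(f"need at least 30 observations, got {x.size}")
        model = LoessRegression(span=self.span, degree=self.degree).fit(x, y)
        grid = np.linspace(x.min(), x.max(), self.grid_points)
        self.curve_ = model.curve(grid)
        fitted = self.curve_.fitted
        deriv = np.gradient(fitted, grid)
        if self.deriv_smooth > 1:
            half = self.deriv_smooth // 2
            deriv = np.convolve(
                np.pad(deriv, half, mode="edge"),
                np.ones(self.deriv_smooth) / self.deriv_smooth,
                mode="valid",
            )
        self.derivative_ = deriv
        scale = np.ptp(fitted)
        self.detected_ = False
        self.x_star_ = float("nan")
        self.pre_slope_ = float("nan")
        self.post_slope_ = float("nan")
        # a flat curve has no turning point; guard against pure noise scales
        if scale <= 1e-12:
            return self
        # detection window: up to where the decline has essentially completed
        done = fitted <= fitted.min() + self.tail_tol * scale
        stop = int(np.argmax(done)) + 1 if done.any() else len(grid)
        if stop < 4:
            return self
        window = deriv[:stop]
        max_rate = np.abs(window).max()
        if max_rate <= 0:
            return self
        threshold = -self.threshold_frac * max_rate
        below = window < threshold
        # sustained decline: below threshold from some index through the
        # window (its closing boundary point itself exempt)
        end = stop - 1
        sustained_from = None
        for i in range(end):
            if below[i:end].all():
                sustained_from = i
                break
        if sustained_from is None or sustained_from == 0:
            # descending at full rate from the very start: no regime change
            return self
        self.detected_ = True
        self.x_star_ = float(grid[sustained_from])
        pre = x < self.x_star_
        post = ~pre
        if pre.sum() >= 2 and np.unique(x[pre]).size >= 2:
            self.pre_slope_ = float(np.polyfit(x[pre], y[pre], 1)[0])
        if post.sum() >= 2 and np.unique(x[post]).size >= 2:
            self.post_slope_ = float(np.polyfit(x[post], y[post], 1)[0])
        return self


@dataclass
class TurningPoint:
    """Turning-point result in plain-record form."""

    x_star: float
    method: str
    pre_slope: float
    post_slope: float
    detected: bool


def turning_point(
    mobiscore,
    cars_per_household,
    span: float = 0.15,
    threshold_frac: float = 0.5,
) -> TurningPoint:
    """Functional wrapper over :class:`TurningPointDetector`."""
    det = TurningPointDetector(span=span, threshold_frac=threshold_frac).fit(
        np.asarray(mobiscore), np.asarray(cars_per_household)
    )
    return TurningPoint(
        x_star=det.x_star_,
        method=f"loess-derivative-threshold(span={span}, frac={threshold_frac})",
        pre_slope=det.pre_slope_,
        post_slope=det.post_slope_,
        detected=det.detected_,
    )


def plot_turning_point(detector: TurningPointDetector, mobiscore, cars, path) -> None:
    """Scatter + smoothed curve + detected turning point marker (PNG)."""
    check_is_fitted(detector, "curve_")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mobiscore, cars, s=8, alpha=0.4, label="sectors")
    c = detector.curve_
    ax.plot(c.eval_x, c.fitted, color="C1", label="LOESS")
    ax.fill_between(c.eval_x, c.ci_low, c.ci_high, color="C1", alpha=0.2)
    if detector.detected_:
        ax.axvline(detector.x_star_, color="C3", ls="--",
                   label=f"turning point {detector.x_star_:.2f}")
    ax.set_xlabel("Mobiscore")
    ax.set_ylabel("cars per household")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
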