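"""Summer/winter concentration ratios and distance-to-road profiles.

The seasonal ratio of a stratum (land-cover class, degree-of-urbanisation
class, sector, or the whole grid) is the ratio of the stratum-mean summer
concentration to the stratum-mean winter concentration — a single fraction
of aggregate concentrations, not a mean of cellwise ratios (the cellwise
variant is available via ``cellwise=True`` for sensitivity). Uncertainty is
a seeded nonparametric bootstrap over cells; the min-max range across cells
is available as an alternative interval.

Distance to roads is a Euclidean distance transform normalised by its grid
maximum, so a "path distance" of e.g. 0.05 reads as a fraction of the
largest road distance on the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import GridMeta, SeasonalField
from .local_regression import LoessFit, LoessRegression

logger = logging.getLogger(__name__)


@dataclass
class RatioResult:
    """Summer/winter ratio of one stratum with winter level and interval."""

    stratum_kind: str  # {"sector", "landcover", "degurba", "overall"}
    stratum_label: object
    ratio: float
    ci_low: float | None
    ci_high: float | None
    winter_mean: float
    winter_sd: float
    area_share: float
    n_cells: int
    interval: str = "bootstrap"

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"ratio must be > 0, got {self.ratio}")
        if self.ci_low is not None and not (self.ci_low <= self.ratio <= self.ci_high):
            raise ValueError("interval must bracket the ratio")
        if self.stratum_kind == "overall" and abs(self.area_share - 1.0) > 1e-12:
            raise ValueError("overall stratum must have area_share 1")


@dataclass
class DistanceField:
    """Per-cell distance to the nearest road cell, as a fraction of the grid maximum."""

    values: np.ndarray  # in [0, 1]; 0 on road cells
    max_distance: float  # map units, the normalisation constant


def sector_ratio(exposure: pd.DataFrame, pollutant: str) -> pd.Series:
    """Summer mean / winter mean per sector from an ExposureTable."""
    sub = exposure[exposure["pollutant"] == pollutant]
    summer = sub[sub["season"] == "summer"].set_index("sector_id")["mean_ugm3"]
    winter = sub[sub["season"] == "winter"].set_index("sector_id")["mean_ugm3"]
    if summer.empty or winter.empty:
        raise ValueError(f"summer and winter means required for {pollutant!r}")
    winter = winter.reindex(summer.index)
    if (winter <= 0).any():
        bad = winter.index[winter <= 0].tolist()
        raise ValueError(f"non-positive winter mean for sector(s) {bad}")
    out = summer / winter
    out.name = "summer_winter_ratio"
    return out


def _ratio_bootstrap(
    summer: np.ndarray, winter: np.ndarray, n_boot: int, rng: np.random.Generator,
) -> tuple[float, float]:
    n = summer.size
    idx = rng.integers(0, n, size=(n_boot, n))
    s = summer[idx].sum(axis=1)
    w = winter[idx].sum(axis=1)
    ok = w > 0
    ratios = s[ok] / w[ok]
    return float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5))


def stratified_ratio(
    summer_field: SeasonalField,
    winter_field: SeasonalField,
    strata: np.ndarray,
    kind: str,
    labels: dict | None = None,
    cellwise: bool = False,
    interval: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[RatioResult]:
    """Summer/winter ratio per stratum of a cell partition.

    ``strata`` is an integer array of the grid shape; negative entries are
    outside every stratum. ``interval`` is "bootstrap" (percentile 2.5/97.5
    over cell resamples), "range" (min-max of cellwise ratios), or "none".
    Empty strata are omitted with a warning.
    """
    su, wi = summer_field.values, winter_field.values
    if su.shape != wi.shape or su.shape != strata.shape:
        raise ValueError("summer, winter and strata grids must share a shape")
    valid = np.isfinite(su) & np.isfinite(wi) & (strata >= 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid cells")
    rng = np.random.default_rng(seed)
    results: list[RatioResult] = []
    for k in np.unique(strata[strata >= 0]):
        mask = valid & (strata == k)
        n_k = int(mask.sum())
        if n_k == 0:
            logger.warning("stratum %r is empty; omitted", k)
            continue
        s_cells, w_cells = su[mask], wi[mask]
        if w_cells.mean() <= 0:
            logger.warning("stratum %r has non-positive winter mean; omitted", k)
            continue
        if cellwise:
            ratio = float(np.mean(s_cells / w_cells))
        else:
            ratio = float(s_cells.mean() / w_cells.mean())
        lo = hi = None
        if interval == "bootstrap" and n_k >= 2:
            lo, hi = _ratio_bootstrap(s_cells, w_cells, n_boot, rng)
            lo, hi = min(lo, ratio), max(hi, ratio)
        elif interval == "range":
            cw = s_cells / np.where(w_cells > 0, w_cells, np.nan)
            lo, hi = float(np.nanmin(cw)), float(np.nanmax(cw))
            lo, hi = min(lo, ratio), max(hi, ratio)
        results.append(
            RatioResult(
                stratum_kind=kind,
                stratum_label=labels.get(int(k), int(k)) if labels else int(k),
                ratio=ratio,
                ci_low=lo,
                ci_high=hi,
                winter_mean=float(w_cells.mean()),
                winter_sd=float(w_cells.std(ddof=0)),
                area_share=n_k / n_valid,
                n_cells=n_k,
                interval=interval,
            )
        )
    return results


def overall_ratio(summer_field: SeasonalField, winter_field: SeasonalField, **kw) -> RatioResult:
    """Grid-wide summer/winter ratio (a single stratum covering everything)."""
    strata = np.zeros_like(summer_field.values, dtype=int)
    strata[~(np.isfinite(summer_field.values) & np.isfinite(winter_field.values))] = -1
    (res,) = stratified_ratio(summer_field, winter_field, strata, kind="overall", **kw)
    return res


def ratios_to_frame(results: list[RatioResult]) -> pd.DataFrame:
    """Tabulate RatioResults with the report-table column layout."""
    return pd.DataFrame(
        {
            "stratum_kind": [r.stratum_kind for r in results],
            "stratum": [r.stratum_label for r in results],
            "winter_mean_ugm3": [r.winter_mean for r in results],
            "winter_sd_ugm3": [r.winter_sd for r in results],
            "ratio": [r.ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "area_share": [r.area_share for r in results],
            "n_cells": [r.n_cells for r in results],
            "interval": [r.interval for r in results],
        }
    )


def distance_transform(road_mask: np.ndarray, meta: GridMeta) -> DistanceField:
    """Normalised Euclidean distance from each cell center to the nearest road cell.

    ``road_mask`` is boolean (True on road cells). The raw distances (map
    units) are divided by the grid maximum so values live in [0, 1].
    """
    road_mask = np.asarray(road_mask, dtype=bool)
    if not road_mask.any():
        raise ValueError("road mask is empty; at least one road cell required")
    dist = ndimage.distance_transform_edt(~road_mask, sampling=meta.cell_size)
    d_max = float(dist.max())
    if d_max == 0:  # every cell is road
        return DistanceField(values=np.zeros_like(dist), max_distance=0.0)
    return DistanceField(values=dist / d_max, max_distance=d_max)


@dataclass
class DistanceProfile:
    """Concentration vs normalised road distance: LOESS curve + straight line."""

    loess: LoessFit
    linear_intercept: float
    linear_slope: float
    pollutant: str
    season: str


def distance_profile(
    fld: SeasonalField,
    dist: DistanceField,
    span: float = 0.75,
    degree: int = 1,
    eval_points: int = 50,
    max_cells: int = 20000,
    seed: int = 0,
) -> DistanceProfile:
    """LOESS (plus ordinary linear) fit of concentration against road distance.

    Cells beyond ``max_cells`` are subsampled with the seeded generator to
    keep the local fits tractable on large grids.
    """
    valid = fld.mask
    x = dist.values[valid].ravel()
    y = fld.values[valid].ravel()
    if x.size < 20:
        raise ValueError(f"need at least 20 cells for a distance profile, got {x.size}")
    if np.unique(x).size < 3:
        raise ValueError("distance values are (nearly) constant; profile undefined")
    if x.size > max_cells:
        keep = np.random.default_rng(seed).choice(x.size, size=max_cells, replace=False)
        x, y = x[keep], y[keep]
    model = LoessRegression(span=span, degree=degree).fit(x, y)
    eval_x = np.linspace(x.min(), x.max(), eval_points)
    fit = model.curve(eval_x)
    slope, intercept = np.polyfit(x, y, 1)
    return DistanceProfile(
        loess=fit,
        linear_intercept=float(intercept),
        linear_slope=float(slope),
        pollutant=fld.pollutant,
        season=fld.season,
    )


def percent_decline(c_origin: float, c_at_d: float, ndigits: int | None = 1) -> float:
    """Percent decrease from the curve value at the origin to the value at distance d.

    ``percent_decline(12.0, 6.0) == 50.0``.
    """
    if c_origin <= 0:
        raise ValueError(f"origin concentration must be > 0, got {c_origin}")
    pct = 100.0 * (c_origin - c_at_d) / c_origin
    return round(pct, ndigits) if ndigits is not None else pct
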