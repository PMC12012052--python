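"""Sector-level exposure aggregation and seasonal summaries.

Gridded seasonal concentrations are averaged over the member cells of each
statistical sector (zonal statistics); the annual sector mean is the
unweighted mean of the four seasonal means. Seasonal contribution shares are
the population-weighted seasonal means normalised to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SEASONS, SeasonalField, SectorFrame

logger = logging.getLogger(__name__)


@dataclass
class SeasonalShares:
    """Fraction of annual residential exposure attributable to each season."""

    pollutant: str
    shares: dict[str, float]
    weighted: bool = True

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"seasonal shares must sum to 1, got {total}")
        for s, v in self.shares.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"share for {s} outside [0, 1]: {v}")


def zonal_mean(fld: SeasonalField, sectors: SectorFrame) -> pd.DataFrame:
    """Per-sector arithmetic mean of member-cell values, nodata excluded.

    Returns an ExposureTable fragment with columns
    (sector_id, pollutant, season, mean_ugm3, n_cells).
    """
    m = sectors.membership
    vals = fld.values[m["row"].to_numpy(), m["col"].to_numpy()]
    ok = np.isfinite(vals)
    sid = m["sector_id"].to_numpy()
    agg = (
        pd.DataFrame({"sector_id": sid[ok], "value": vals[ok]})
        .groupby("sector_id")["value"]
        .agg(["mean", "size"])
    )
    missing = sorted(int(s) for s in set(sectors.sector_ids) - set(agg.index))
    if missing:
        raise ValueError(f"sectors with all-nodata cells in {fld.pollutant}/{fld.season}: {missing}")
    out = agg.reset_index().rename(columns={"mean": "mean_ugm3", "size": "n_cells"})
    out.insert(1, "pollutant", fld.pollutant)
    out.insert(2, "season", fld.season)
    return out.sort_values("sector_id", ignore_index=True)


def build_exposure_table(fields: list[SeasonalField], sectors: SectorFrame) -> pd.DataFrame:
    """Zonal means for every field, stacked into one long ExposureTable."""
    parts = [zonal_mean(f, sectors) for f in fields]
    return pd.concat(parts, ignore_index=True)


def annual_means(exposure: pd.DataFrame, pollutant: str) -> pd.Series:
    """Annual sector mean: unweighted mean of the four seasonal means."""
    sub = exposure[exposure["pollutant"] == pollutant]
    have = set(sub["season"].unique())
    missing = [s for s in SEASONS if s not in have]
    if missing:
        raise ValueError(f"missing season(s) for {pollutant}: {missing}")
    return sub.groupby("sector_id")["mean_ugm3"].mean()


def population_weighted_mean(values, population) -> float:
    """Population-weighted mean: sum(pop_i * v_i) / sum(pop_i).

    Zero-population sectors carry no weight; all-zero populations are an error.
    """
    v = np.asarray(values, dtype=float)
    pop = np.asarray(population, dtype=float)
    if v.shape != pop.shape:
        raise ValueError("values and population must align")
    if (pop < 0).any():
        raise ValueError("negative population")
    total = pop.sum()
    if total == 0:
        raise ValueError("all-zero population; population-weighted mean undefined")
    return float((pop * v).sum() / total)


def seasonal_shares(
    exposure: pd.DataFrame,
    sectors: SectorFrame,
    pollutant: str,
    weighted: bool = True,
) -> SeasonalShares:
    """Contribution of each season to annual residential exposure.

    share(s) = PWM(s) / sum_s' PWM(s'), with PWM the population-weighted mean
    of sector seasonal means (set ``weighted=False`` for the unweighted
    sensitivity variant).
    """
    sub = exposure[exposure["pollutant"] == pollutant]
    pop = sectors.attributes.set_index("sector_id")["population"]
    pwm = {}
    for season in SEASONS:
        block = sub[sub["season"] == season].set_index("sector_id")["mean_ugm3"]
        if block.empty:
            raise ValueError(f"missing season {season!r} for pollutant {pollutant!r}")
        if weighted:
            pwm[season] = population_weighted_mean(
                block.to_numpy(), pop.reindex(block.index).to_numpy()
            )
        else:
            pwm[season] = float(block.mean())
    total = sum(pwm.values())
    shares = {s: v / total for s, v in pwm.items()}
    # remove float residue so the shares-sum-to-1 invariant holds exactly
    resid = 1.0 - sum(shares.values())
    shares[SEASONS[0]] += resid
    return SeasonalShares(pollutant=pollutant, shares=shares, weighted=weighted)
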