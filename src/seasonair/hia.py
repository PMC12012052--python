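"""Health impact assessment: preventable fraction under the WHO-guideline counterfactual.

A literature relative risk per 10 ug/m3 (RR10, with 95% CI) is rescaled to a
sector's exposure CON via log-linearity,

    RR_exposure = exp(ln(RR10) / 10 * CON),

and the preventable fraction is PF = 1 - 1/RR. By default CON is the excess
of the annual sector mean over the WHO guideline, clipped at zero — the
counterfactual of exactly reaching the guideline, under which a sector at or
below the guideline has PF = 0. The alternative reading (CON = the raw
concentration, counterfactual of zero exposure) is available with
``counterfactual="zero"``.

RR10 uncertainty is propagated by Monte Carlo: draws from a triangular
distribution with mode at the point estimate and support on the 95% CI,
sampled by inverse CDF on a seeded uniform stream (10,000 iterations by
default). National aggregation is the population-weighted mean of sector
PFs; PF-of-weighted-mean-exposure is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import annual_means, population_weighted_mean
from .io_formats import SectorFrame

logger = logging.getLogger(__name__)

#: WHO (2021) long-term air quality guidelines, ug/m3
WHO_GUIDELINES = {"NO2": 10.0, "PM25": 5.0}

#: ELAPSE meta-analysis relative risks for adult all-cause mortality,
#: per 10 ug/m3 increment (point estimate, 95% CI)
ELAPSE_RR10 = {
    "NO2": (1.045, 1.026, 1.065),
    "PM25": (1.118, 1.060, 1.179),
}


@dataclass(frozen=True)
class ExposureResponse:
    """Exposure-response configuration for one pollutant."""

    pollutant: str
    rr10: float
    rr10_low: float
    rr10_high: float
    guideline: float

    def __post_init__(self) -> None:
        if not (0 < self.rr10_low <= self.rr10 <= self.rr10_high):
            raise ValueError(
                f"need 0 < rr10_low <= rr10 <= rr10_high, got "
                f"({self.rr10_low}, {self.rr10}, {self.rr10_high})"
            )
        if self.guideline < 0:
            raise ValueError("guideline must be >= 0")

    @classmethod
    def default(cls, pollutant: str) -> "ExposureResponse":
        """ELAPSE all-cause-mortality RR10 + WHO 2021 guideline for the pollutant."""
        rr, lo, hi = ELAPSE_RR10[pollutant]
        return cls(pollutant=pollutant, rr10=rr, rr10_low=lo, rr10_high=hi,
                   guideline=WHO_GUIDELINES[pollutant])


@dataclass
class PFResult:
    """Preventable fraction with Monte Carlo interval."""

    level: str  # {"sector", "national"}
    pollutant: str
    pf: float
    pf_low: float
    pf_high: float
    rr_exposure: float
    n_iterations: int
    seed: int
    counterfactual: str = "guideline"
    sector_id: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pf < 1):
            raise ValueError(f"PF must be in [0, 1), got {self.pf}")
        if not (self.pf_low <= self.pf <= self.pf_high):
            raise ValueError("MC interval must bracket the point estimate")


def excess_concentration(conc, guideline: float):
    """Exposure above the guideline, clipped at zero: max(conc - guideline, 0)."""
    conc = np.asarray(conc, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    out = np.clip(conc - guideline, 0.0, None)
    return float(out) if out.ndim == 0 else out


def rescale_rr(rr10, con):
    """Rescale RR per 10 ug/m3 to an arbitrary increment: exp(ln(rr10)/10 * con)."""
    rr10 = np.asarray(rr10, dtype=float)
    con = np.asarray(con, dtype=float)
    if (rr10 <= 0).any():
        raise ValueError("rr10 must be > 0")
    if (con < 0).any():
        raise ValueError("concentration increment must be >= 0")
    out = np.exp(np.log(rr10) / 10.0 * con)
    return float(out) if out.ndim == 0 else out


def preventable_fraction(rr):
    """PF = 1 - 1/RR. RR < 1 (protective) is clipped to PF = 0 with a warning."""
    rr = np.asarray(rr, dtype=float)
    if (rr < 1).any():
        logger.warning("RR < 1 encountered; preventable fraction clipped to 0")
    out = np.clip(1.0 - 1.0 / rr, 0.0, None)
    return float(out) if out.ndim == 0 else out


def sample_rr_triangular(er: ExposureResponse, n: int, seed: int) -> np.ndarray:
    """Draw RR10 values from Triangular(a=rr10_low, c=rr10, b=rr10_high).

    Inverse-CDF on a seeded uniform stream, so the draws are deterministic
    given the seed. A degenerate distribution (a == b) returns the constant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a, c, b = er.rr10_low, er.rr10, er.rr10_high
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    if b == a:
        return np.full(n, a)
    fc = (c - a) / (b - a)
    left = u < fc
    out = np.empty(n)
    out[left] = a + np.sqrt(u[left] * (b - a) * (c - a))
    out[~left] = b - np.sqrt((1.0 - u[~left]) * (b - a) * (b - c))
    return np.clip(out, a, b)


def pf_with_uncertainty(
    exposure: pd.DataFrame,
    sectors: SectorFrame,
    er: ExposureResponse,
    n_iter: int = 10_000,
    seed: int = 0,
    counterfactual: str = "guideline",
    aggregation: str = "weighted_pf",
) -> tuple[PFResult, list[PFResult]]:
    """Sector and national preventable fractions with Monte Carlo intervals.

    Per iteration an RR10 draw is rescaled to every sector's annual CON and
    the national PF is the population-weighted mean of sector PFs
    (``aggregation="pf_of_mean"`` instead computes the PF of the
    population-weighted mean exposure). Point estimates use the RR10 mode;
    intervals are the 2.5/97.5 Monte Carlo percentiles.
    """
    if counterfactual not in ("guideline", "zero"):
        raise ValueError(f"unknown counterfactual mode {counterfactual!r}")
    if aggregation not in ("weighted_pf", "pf_of_mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ann = annual_means(exposure, er.pollutant)  # raises if a season is missing
    attrs = sectors.attributes.set_index("sector_id")
    ann = ann.reindex(attrs.index)
    if ann.isna().any():
        raise ValueError(
            f"missing annual means for sectors {ann.index[ann.isna()].tolist()}"
        )
    conc = ann.to_numpy()
    pop = attrs["population"].to_numpy(dtype=float)
    if counterfactual == "guideline":
        con = excess_concentration(conc, er.guideline)
    else:
        con = np.asarray(conc, dtype=float)

    def _pf_matrix(rr10_draws: np.ndarray) -> np.ndarray:
        # (n_draws, n_sectors)
        rr = np.exp(np.log(rr10_draws)[:, None] / 10.0 * con[None, :])
        return np.clip(1.0 - 1.0 / rr, 0.0, None)

    draws = sample_rr_triangular(er, n_iter, seed)
    pf_iter = _pf_matrix(draws)
    pf_point = _pf_matrix(np.array([er.rr10]))[0]

    if aggregation == "weighted_pf":
        national_iter = (pf_iter * pop[None, :]).sum(axis=1) / pop.sum()
        national_point = population_weighted_mean(pf_point, pop)
    else:
        mean_con = population_weighted_mean(con, pop)
        national_iter = np.clip(
            1.0 - 1.0 / np.exp(np.log(draws) / 10.0 * mean_con), 0.0, None
        )
        national_point = preventable_fraction(rescale_rr(er.rr10, mean_con))

    lo, hi = np.percentile(national_iter, [2.5, 97.5])
    national = PFResult(
        level="national",
        pollutant=er.pollutant,
        pf=float(national_point),
        pf_low=float(min(lo, national_point)),
        pf_high=float(max(hi, national_point)),
        rr_exposure=float(rescale_rr(er.rr10, population_weighted_mean(con, pop))),
        n_iterations=n_iter,
        seed=seed,
        counterfactual=counterfactual,
    )
    sector_results: list[PFResult] = []
    sec_lo = np.percentile(pf_iter, 2.5, axis=0)
    sec_hi = np.percentile(pf_iter, 97.5, axis=0)
    for i, sid in enumerate(attrs.index):
        sector_results.append(
            PFResult(
                level="sector",
                pollutant=er.pollutant,
                pf=float(pf_point[i]),
                pf_low=float(min(sec_lo[i], pf_point[i])),
                pf_high=float(max(sec_hi[i], pf_point[i])),
                rr_exposure=float(rescale_rr(er.rr10, con[i])),
                n_iterations=n_iter,
                seed=seed,
                counterfactual=counterfactual,
                sector_id=int(sid),
            )
        )
    return national, sector_results


def pf_to_frame(national: PFResult, sector_results: list[PFResult]) -> pd.DataFrame:
    rows = [national] + sector_results
    return pd.DataFrame(
        {
            "level": [r.level for r in rows],
            "sector_id": [r.sector_id for r in rows],
            "pollutant": [r.pollutant for r in rows],
            "pf": [r.pf for r in rows],
            "pf_low": [r.pf_low for r in rows],
            "pf_high": [r.pf_high for r in rows],
            "rr_exposure": [r.rr_exposure for r in rows],
            "n_iter": [r.n_iterations for r in rows],
            "seed": [r.seed for r in rows],
            "counterfactual_mode": [r.counterfactual for r in rows],
        }
    )
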