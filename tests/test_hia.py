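"""Preventable-fraction arithmetic, triangular Monte Carlo, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seasonair.exposure import build_exposure_table
from seasonair.hia import (
    ExposureResponse,
    excess_concentration,
    pf_with_uncertainty,
    preventable_fraction,
    rescale_rr,
    sample_rr_triangular,
)
from seasonair.io_formats import SEASONS, SectorFrame

NO2_ER = ExposureResponse("NO2", 1.045, 1.026, 1.065, 10.0)
PM25_ER = ExposureResponse("PM25", 1.118, 1.060, 1.179, 5.0)


class TestFormulas:
    def test_excess_concentration(self):
        assert excess_concentration(12.0, 10.0) == 2.0
        assert excess_concentration(8.0, 10.0) == 0.0
        assert excess_concentration(5.0, 5.0) == 0.0

    def test_rescale_rr_fixed_points(self):
        assert rescale_rr(1.045, 10.0) == pytest.approx(1.045, abs=1e-15)
        assert rescale_rr(1.118, 0.0) == 1.0
        # doubling the increment squares the risk under log-linearity
        assert rescale_rr(1.118, 20.0) == pytest.approx(1.118**2, abs=1e-12)
        assert rescale_rr(1.118, 20.0) == pytest.approx(1.249924, abs=5e-7)

    def test_preventable_fraction(self):
        assert preventable_fraction(1.0) == 0.0
        assert preventable_fraction(2.0) == 0.5
        assert preventable_fraction(1.045) == pytest.approx(0.04306220, abs=1e-8)

    def test_protective_rr_clipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="seasonair.hia"):
            assert preventable_fraction(0.9) == 0.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_pf_monotone_in_rr_and_con(self):
        cons = np.linspace(0, 40, 25)
        pf = preventable_fraction(rescale_rr(1.045, cons))
        assert (np.diff(pf) >= 0).all()
        rrs = np.linspace(1.0, 1.4, 25)
        pf2 = preventable_fraction(rescale_rr(rrs, 15.0))
        assert (np.diff(pf2) >= 0).all()

    def test_invalid_exposure_response(self):
        with pytest.raises(ValueError):
            ExposureResponse("NO2", 1.0, 1.1, 1.2, 10.0)


class TestTriangularSampling:
    def test_support(self):
        draws = sample_rr_triangular(NO2_ER, 20_000, seed=0)
        assert draws.min() >= 1.026
        assert draws.max() <= 1.065

    def test_mean_matches_closed_form(self):
        n = 100_000
        draws = sample_rr_triangular(PM25_ER, n, seed=1)
        a, c, b = 1.060, 1.118, 1.179
        expected = (a + b + c) / 3
        var = (a**2 + b**2 + c**2 - a * b - a * c - b * c) / 18
        se = np.sqrt(var / n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_cdf_at_mode_matches_closed_form(self):
        n = 100_000
        draws = sample_rr_triangular(NO2_ER, n, seed=2)
        a, c, b = 1.026, 1.045, 1.065
        expected = (c - a) / (b - a)
        ecdf = (draws <= c).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(ecdf - expected) < 4 * se

    def test_distribution_matches_scipy_triang(self):
        """Full-distribution cross-check against scipy's triangular CDF."""
        draws = sample_rr_triangular(NO2_ER, 50_000, seed=3)
        a, c, b = 1.026, 1.045, 1.065
        dist = stats.triang(c=(c - a) / (b - a), loc=a, scale=b - a)
        ks = stats.kstest(draws, dist.cdf)
        assert ks.pvalue > 0.01

    def test_degenerate_interval(self):
        er = ExposureResponse("NO2", 1.05, 1.05, 1.05, 10.0)
        draws = sample_rr_triangular(er, 100, seed=0)
        assert (draws == 1.05).all()

    def test_deterministic_given_seed(self):
        a = sample_rr_triangular(NO2_ER, 1000, seed=7)
        b = sample_rr_triangular(NO2_ER, 1000, seed=7)
        np.testing.assert_array_equal(a, b)


def _toy_region(annual_by_sector, populations):
    """Sectors of one cell each with constant fields across seasons."""
    n = len(annual_by_sector)
    attrs = pd.DataFrame(
        {
            "sector_id": range(n),
            "population": populations,
            "landcover": "urban_fabric",
            "degurba": 1,
        }
    )
    membership = pd.DataFrame({"sector_id": range(n), "row": 0, "col": range(n)})
    sectors = SectorFrame(attrs, membership)
    rows = []
    for sid, v in enumerate(annual_by_sector):
        for season in SEASONS:
            rows.append((sid, "NO2", season, v, 1))
    table = pd.DataFrame(
        rows, columns=["sector_id", "pollutant", "season", "mean_ugm3", "n_cells"]
    )
    return table, sectors


class TestPFWithUncertainty:
    def test_all_sectors_at_guideline_gives_zero_pf(self):
        table, sectors = _toy_region([10.0, 10.0, 10.0], [100, 200, 300])
        national, per_sector = pf_with_uncertainty(table, sectors, NO2_ER, n_iter=500, seed=0)
        assert national.pf == 0.0
        assert national.pf_low == national.pf_high == 0.0
        assert all(r.pf == 0.0 for r in per_sector)

    def test_single_sector_composition(self):
        # CON = 20 - 10 = 10 above guideline -> PF = 1 - 1/1.045
        table, sectors = _toy_region([20.0], [500])
        national, _ = pf_with_uncertainty(table, sectors, NO2_ER, n_iter=500, seed=0)
        assert national.pf == pytest.approx(1 - 1 / 1.045, abs=1e-12)

    def test_degenerate_triangular_reproduces_deterministic_pf(self):
        er = ExposureResponse("NO2", 1.045, 1.045, 1.045, 10.0)
        table, sectors = _toy_region([20.0, 14.0], [100, 300])
        national, _ = pf_with_uncertainty(table, sectors, er, n_iter=200, seed=0)
        assert national.pf_low == pytest.approx(national.pf, abs=1e-12)
        assert national.pf_high == pytest.approx(national.pf, abs=1e-12)

    def test_national_between_sector_extremes(self):
        table, sectors = _toy_region([12.0, 25.0, 40.0], [100, 100, 100])
        national, per_sector = pf_with_uncertainty(table, sectors, NO2_ER, n_iter=500, seed=0)
        pfs = [r.pf for r in per_sector]
        assert min(pfs) <= national.pf <= max(pfs)

    def test_point_estimate_seed_invariant_and_ci_stable(self):
        table, sectors = _toy_region([15.0, 22.0, 30.0], [400, 500, 600])
        results = [
            pf_with_uncertainty(table, sectors, NO2_ER, n_iter=10_000, seed=s)[0]
            for s in (1, 2, 3)
        ]
        assert len({r.pf for r in results}) == 1
        los = [r.pf_low for r in results]
        his = [r.pf_high for r in results]
        assert (max(los) - min(los)) / np.mean(los) < 0.05
        assert (max(his) - min(his)) / np.mean(his) < 0.05

    def test_ci_brackets_point_and_rr_bounds_bracket_ci(self):
        table, sectors = _toy_region([18.0, 26.0], [300, 700])
        national, _ = pf_with_uncertainty(table, sectors, NO2_ER, n_iter=5000, seed=4)
        assert national.pf_low <= national.pf <= national.pf_high
        # PF at the triangular endpoints bounds the MC interval outward
        lo_er = ExposureResponse("NO2", 1.026, 1.026, 1.026, 10.0)
        hi_er = ExposureResponse("NO2", 1.065, 1.065, 1.065, 10.0)
        pf_lo = pf_with_uncertainty(table, sectors, lo_er, n_iter=10, seed=0)[0].pf
        pf_hi = pf_with_uncertainty(table, sectors, hi_er, n_iter=10, seed=0)[0].pf
        assert pf_lo <= national.pf_low
        assert pf_hi >= national.pf_high

    def test_counterfactual_zero_uses_raw_concentration(self):
        table, sectors = _toy_region([10.0], [100])
        guide, _ = pf_with_uncertainty(table, sectors, NO2_ER, n_iter=100, seed=0)
        zero, _ = pf_with_uncertainty(
            table, sectors, NO2_ER, n_iter=100, seed=0, counterfactual="zero"
        )
        assert guide.pf == 0.0
        assert zero.pf == pytest.approx(1 - 1 / 1.045, abs=1e-12)

    def test_missing_season_aborts(self, noisefree_region):
        table = build_exposure_table(
            [noisefree_region.fields[("NO2", s)] for s in ("winter", "spring", "summer")],
            noisefree_region.sectors,
        )
        with pytest.raises(ValueError, match="autumn"):
            pf_with_uncertainty(table, noisefree_region.sectors, NO2_ER, n_iter=10, seed=0)
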