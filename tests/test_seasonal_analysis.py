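"""Ratios, stratification, distance transform and profiles, percent declines."""

import numpy as np
import pandas as pd
import pytest

from seasonair.exposure import build_exposure_table
from seasonair.io_formats import GridMeta, SeasonalField
from seasonair.seasonal_analysis import (
    distance_profile,
    distance_transform,
    overall_ratio,
    percent_decline,
    sector_ratio,
    stratified_ratio,
)


def field_of(values, pollutant="NO2", season="winter"):
    values = np.asarray(values, dtype=float)
    meta = GridMeta(rows=values.shape[0], cols=values.shape[1],
                    y_origin=float(values.shape[0]))
    return SeasonalField(pollutant, season, values, meta)


class TestSectorRatio:
    def test_identical_fields_ratio_one(self, noisefree_region):
        table = build_exposure_table(
            [
                noisefree_region.fields[("NO2", "winter")],
                SeasonalField(
                    "NO2", "summer",
                    noisefree_region.fields[("NO2", "winter")].values,
                    noisefree_region.fields[("NO2", "winter")].meta,
                ),
            ],
            noisefree_region.sectors,
        )
        np.testing.assert_allclose(sector_ratio(table, "NO2"), 1.0, atol=1e-12)

    def test_simple_arithmetic(self):
        table = pd.DataFrame(
            {
                "sector_id": [0, 0],
                "pollutant": ["NO2", "NO2"],
                "season": ["summer", "winter"],
                "mean_ugm3": [6.0, 12.0],
                "n_cells": [4, 4],
            }
        )
        assert sector_ratio(table, "NO2")[0] == pytest.approx(0.5)

    def test_nonpositive_winter_rejected(self):
        table = pd.DataFrame(
            {
                "sector_id": [0, 0],
                "pollutant": ["NO2", "NO2"],
                "season": ["summer", "winter"],
                "mean_ugm3": [6.0, 0.0],
                "n_cells": [4, 4],
            }
        )
        with pytest.raises(ValueError, match="winter"):
            sector_ratio(table, "NO2")


class TestStratifiedRatio:
    def test_single_stratum_equals_overall(self, rng):
        su = field_of(rng.uniform(3, 9, (10, 10)), season="summer")
        wi = field_of(rng.uniform(10, 20, (10, 10)), season="winter")
        strata = np.zeros((10, 10), dtype=int)
        (res,) = stratified_ratio(su, wi, strata, kind="overall", interval="none")
        assert res.ratio == pytest.approx(su.values.mean() / wi.values.mean())
        assert res.area_share == 1.0

    def test_recovers_planted_ratios_exactly(self, noisefree_region):
        """Noise-free road and far-background strata hit the planted ratios to 1e-9."""
        from seasonair.synthetic_region import distance_cells

        spec = noisefree_region.spec
        d = distance_cells(spec)
        strata = np.full(spec.grid_shape, -1, dtype=int)
        strata[d == 0] = 0  # road stratum
        strata[d > 20 * spec.decay_scale] = 1  # far background
        for pollutant in ("NO2", "PM25"):
            res = stratified_ratio(
                noisefree_region.fields[(pollutant, "summer")],
                noisefree_region.fields[(pollutant, "winter")],
                strata, kind="landcover", interval="none",
            )
            by_label = {r.stratum_label: r.ratio for r in res}
            assert by_label[0] == pytest.approx(
                spec.planted_ratio_road[pollutant], abs=1e-9
            )
            assert by_label[1] == pytest.approx(
                spec.planted_ratio_background[pollutant], abs=1e-9
            )

    def test_area_shares_partition(self, noisy_region):
        res = stratified_ratio(
            noisy_region.fields[("NO2", "summer")],
            noisy_region.fields[("NO2", "winter")],
            noisy_region.landcover, kind="landcover", interval="none",
        )
        assert sum(r.area_share for r in res) == pytest.approx(1.0)

    def test_scale_invariance(self, noisy_region):
        su = noisy_region.fields[("NO2", "summer")]
        wi = noisy_region.fields[("NO2", "winter")]
        scaled_su = SeasonalField("NO2", "summer", 4.2 * su.values, su.meta)
        scaled_wi = SeasonalField("NO2", "winter", 4.2 * wi.values, wi.meta)
        strata = noisy_region.landcover
        a = stratified_ratio(su, wi, strata, kind="landcover", interval="none")
        b = stratified_ratio(scaled_su, scaled_wi, strata, kind="landcover", interval="none")
        for ra, rb in zip(a, b):
            assert ra.ratio == pytest.approx(rb.ratio, rel=1e-12)

    def test_bootstrap_interval_brackets_ratio(self, noisy_region):
        res = stratified_ratio(
            noisy_region.fields[("NO2", "summer")],
            noisy_region.fields[("NO2", "winter")],
            noisy_region.landcover, kind="landcover", n_boot=200, seed=1,
        )
        for r in res:
            assert r.ci_low <= r.ratio <= r.ci_high

    def test_winter_weighted_cell_ratios_average_to_overall(self, rng):
        """Singleton-cell strata, weighted by winter mass, recombine to the
        overall ratio of aggregate concentrations."""
        su = rng.uniform(3, 9, (6, 6))
        wi = rng.uniform(10, 20, (6, 6))
        cell_ratios = su / wi
        overall = su.mean() / wi.mean()
        assert np.average(cell_ratios, weights=wi) == pytest.approx(overall)

    def test_road_exceeds_background(self, noisy_region):
        """Traffic cells dilute least in summer - ordering matches observation."""
        truth = noisy_region.truth.stratum_ratios["landcover"]["NO2"]
        assert truth["road_rail"] > truth["forest"]


class TestDistanceTransform:
    def test_zero_on_roads_and_normalised(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[:, 4] = True
        meta = GridMeta(rows=5, cols=9, y_origin=5.0)
        dist = distance_transform(mask, meta)
        assert (dist.values[:, 4] == 0).all()
        assert dist.values.max() == pytest.approx(1.0)

    def test_single_road_column_proportional_offsets(self):
        mask = np.zeros((1, 11), dtype=bool)
        mask[0, 0] = True
        meta = GridMeta(rows=1, cols=11, y_origin=1.0)
        dist = distance_transform(mask, meta)
        np.testing.assert_allclose(dist.values[0], np.arange(11) / 10.0)

    def test_matches_brute_force_nearest_road(self, rng):
        for _ in range(5):
            mask = rng.uniform(size=(30, 30)) < 0.02
            if not mask.any():
                mask[7, 12] = True
            meta = GridMeta(rows=30, cols=30, y_origin=30.0)
            dist = distance_transform(mask, meta)
            roads = np.argwhere(mask)
            brute = np.empty((30, 30))
            for r in range(30):
                for c in range(30):
                    brute[r, c] = np.sqrt(((roads - (r, c)) ** 2).sum(axis=1)).min()
            np.testing.assert_allclose(dist.values, brute / brute.max(), atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_transform(np.zeros((4, 4), dtype=bool), GridMeta(4, 4, y_origin=4.0))


class TestDistanceProfile:
    def test_linear_field_reproduced(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, 0] = True
        meta = GridMeta(rows=20, cols=20, y_origin=20.0)
        dist = distance_transform(mask, meta)
        fld = field_of(30.0 - 12.0 * dist.values, season="winter")
        prof = distance_profile(fld, dist, span=0.5)
        np.testing.assert_allclose(
            prof.loess.fitted, 30.0 - 12.0 * prof.loess.eval_x, atol=1e-8
        )
        assert prof.linear_slope == pytest.approx(-12.0, abs=1e-8)

    def test_decay_field_origin_value(self, noisefree_region):
        """Fitted value at the road equals background + increment within 2%."""
        spec = noisefree_region.spec
        mask = noisefree_region.road_mask
        dist = distance_transform(mask, spec.meta)
        fld = noisefree_region.fields[("NO2", "winter")]
        prof = distance_profile(fld, dist, span=0.05)
        expected = spec.background_winter["NO2"] + spec.road_increment_winter["NO2"]
        assert prof.loess.fitted[0] == pytest.approx(expected, rel=0.02)

    def test_negative_slope_on_decay_fields(self, noisy_region):
        dist = distance_transform(noisy_region.road_mask, noisy_region.spec.meta)
        prof = distance_profile(noisy_region.fields[("NO2", "winter")], dist)
        assert prof.linear_slope < 0

    def test_too_few_cells_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        meta = GridMeta(3, 3, y_origin=3.0)
        dist = distance_transform(mask, meta)
        with pytest.raises(ValueError, match="20 cells"):
            distance_profile(field_of(np.ones((3, 3))), dist)


class TestPercentDecline:
    @pytest.mark.parametrize(
        "origin,at_d,expected",
        [
            (12.0, 6.0, 50.0),
            (18.5, 13.0, 29.7),
            (12.0, 9.9, 17.5),
            (7.5, 5.5, 26.7),
            (4.4, 4.4, 0.0),
        ],
    )
    def test_examples(self, origin, at_d, expected):
        assert percent_decline(origin, at_d) == pytest.approx(expected)

    def test_nonpositive_origin_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            percent_decline(0.0, 1.0)
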