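"""Vulnerability index, profile weighting, depth regressions, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from soilc14 import (
    assign_depth_bin,
    depth_midpoint,
    depth_rate,
    depth_rates_by_landuse,
    landuse_summary,
    profile_weighted_ages,
    vulnerability_index,
)


class TestVulnerabilityIndex:
    def test_zero_age_gives_zero(self):
        assert vulnerability_index(0.0, 10.0) == 0.0

    def test_one_year_litter_layer(self):
        # ln(1+1)/10: a system age of 1 must not log to zero
        assert vulnerability_index(1.0, 10.0) == pytest.approx(
            math.log(2) / 10.0, rel=1e-12
        )

    def test_peatland_topsoil_magnitude(self):
        assert vulnerability_index(2293.0, 5.0) == pytest.approx(1.548, abs=1e-3)

    def test_zero_roc_reported_missing_not_infinite(self):
        assert math.isnan(vulnerability_index(100.0, 0.0))

    def test_monotone_in_both_arguments(self):
        sas = np.linspace(0.5, 5000, 30)
        rocs = np.linspace(1.0, 60.0, 30)
        vi_sa = [vulnerability_index(s, 10.0) for s in sas]
        vi_roc = [vulnerability_index(100.0, r) for r in rocs]
        assert np.all(np.diff(vi_sa) > 0)
        assert np.all(np.diff(vi_roc) < 0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            vulnerability_index(-1.0, 10.0)


def layer_frame(rows):
    defaults = {
        "tt_median_yr": np.nan,
        "sa_median_yr": np.nan,
        "soc_stock_kg_m2": np.nan,
        "decomposability_ugC_gSOC_h": np.nan,
        "excluded": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestProfileWeightedAges:
    def test_single_layer_returns_itself(self):
        df = layer_frame(
            [
                {
                    "tt_median_yr": 12.0,
                    "sa_median_yr": 80.0,
                    "soc_stock_kg_m2": 3.0,
                    "decomposability_ugC_gSOC_h": 5.0,
                }
            ]
        )
        out = profile_weighted_ages(df)
        assert out["sa_profile_yr"] == pytest.approx(80.0)
        assert out["tt_profile_yr"] == pytest.approx(12.0)

    def test_stock_weighted_system_age(self):
        df = layer_frame(
            [
                {"sa_median_yr": 100.0, "soc_stock_kg_m2": 10.0,
                 "tt_median_yr": 1.0, "decomposability_ugC_gSOC_h": 1.0},
                {"sa_median_yr": 400.0, "soc_stock_kg_m2": 5.0,
                 "tt_median_yr": 1.0, "decomposability_ugC_gSOC_h": 1.0},
            ]
        )
        assert profile_weighted_ages(df)["sa_profile_yr"] == pytest.approx(200.0)

    def test_equal_weights_reduce_to_mean(self):
        df = layer_frame(
            [
                {"tt_median_yr": 10.0, "sa_median_yr": 1.0,
                 "soc_stock_kg_m2": 2.0, "decomposability_ugC_gSOC_h": 3.0},
                {"tt_median_yr": 30.0, "sa_median_yr": 1.0,
                 "soc_stock_kg_m2": 2.0, "decomposability_ugC_gSOC_h": 3.0},
            ]
        )
        assert profile_weighted_ages(df)["tt_profile_yr"] == pytest.approx(20.0)

    def test_excluded_layer_dropped_from_tt_only(self):
        df = layer_frame(
            [
                {"tt_median_yr": 10.0, "sa_median_yr": 100.0,
                 "soc_stock_kg_m2": 1.0, "decomposability_ugC_gSOC_h": 1.0},
                {"tt_median_yr": 99.0, "sa_median_yr": 300.0,
                 "soc_stock_kg_m2": 1.0, "decomposability_ugC_gSOC_h": 1.0,
                 "excluded": True},
            ]
        )
        out = profile_weighted_ages(df)
        assert out["tt_profile_yr"] == pytest.approx(10.0)
        assert out["n_tt_dropped"] == 1
        # SA keeps both layers: the bulk constraint is unaffected by screening
        assert out["sa_profile_yr"] == pytest.approx(200.0)

    def test_all_excluded_gives_missing_with_reason(self):
        df = layer_frame(
            [{"tt_median_yr": 10.0, "sa_median_yr": 100.0,
              "soc_stock_kg_m2": 1.0, "decomposability_ugC_gSOC_h": 1.0,
              "excluded": True}]
        )
        out = profile_weighted_ages(df)
        assert math.isnan(out["tt_profile_yr"])
        assert "excluded" in out["tt_reason"]

    def test_profile_sa_is_convex_combination(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 6)
            df = layer_frame(
                [
                    {"sa_median_yr": float(rng.uniform(5, 3000)),
                     "soc_stock_kg_m2": float(rng.uniform(0.1, 10)),
                     "tt_median_yr": 1.0, "decomposability_ugC_gSOC_h": 1.0}
                    for _ in range(n)
                ]
            )
            out = profile_weighted_ages(df)
            assert df.sa_median_yr.min() <= out["sa_profile_yr"] <= df.sa_median_yr.max()

    def test_weight_switch_changes_weighting(self):
        df = layer_frame(
            [
                {"tt_median_yr": 10.0, "sa_median_yr": 1.0,
                 "soc_stock_kg_m2": 10.0, "decomposability_ugC_gSOC_h": 1.0},
                {"tt_median_yr": 30.0, "sa_median_yr": 1.0,
                 "soc_stock_kg_m2": 1.0, "decomposability_ugC_gSOC_h": 1.0},
            ]
        )
        flux = profile_weighted_ages(df, tt_weight="flux")["tt_profile_yr"]
        per_g = profile_weighted_ages(df, tt_weight="decomposability")["tt_profile_yr"]
        assert flux == pytest.approx((10 * 10 + 30 * 1) / 11.0)
        assert per_g == pytest.approx(20.0)


class TestDepthRate:
    def test_constant_ages_zero_slope(self):
        assert depth_rate([2.5, 7.5, 15.0], [50.0, 50.0, 50.0]) == pytest.approx(0.0)

    def test_two_point_slope(self):
        assert depth_rate([5.0, 15.0], [100.0, 300.0]) == pytest.approx(20.0)

    def test_collinear_third_point_leaves_slope(self):
        assert depth_rate([5.0, 15.0, 25.0], [100.0, 300.0, 500.0]) == pytest.approx(
            20.0
        )

    def test_order_invariance(self):
        a = depth_rate([5.0, 15.0, 30.0], [10.0, 90.0, 200.0])
        b = depth_rate([30.0, 5.0, 15.0], [200.0, 10.0, 90.0])
        assert a == pytest.approx(b, rel=1e-12)

    def test_offset_invariance(self):
        a = depth_rate([5.0, 15.0, 30.0], [10.0, 90.0, 200.0])
        b = depth_rate([5.0, 15.0, 30.0], [1010.0, 1090.0, 1200.0])
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_layer_missing(self):
        assert math.isnan(depth_rate([5.0], [100.0]))

    def test_by_landuse_excludes_organic_layers(self):
        df = pd.DataFrame(
            {
                "land_use": ["forest"] * 3 + ["cropland"] * 2,
                "organic_layer": [True, False, False, False, False],
                "depth_mid_cm": [np.nan, 2.5, 15.0, 2.5, 30.0],
                "sa_median_yr": [5.0, 50.0, 300.0, 40.0, 150.0],
            }
        )
        slopes, headline = depth_rates_by_landuse(df, "sa_median_yr")
        assert slopes["forest"] == pytest.approx((300 - 50) / 12.5)
        assert slopes["cropland"] == pytest.approx((150 - 40) / 27.5)
        assert headline == pytest.approx(np.mean(list(slopes)))


class TestDepthBins:
    @pytest.mark.parametrize(
        "top, bottom, organic, expected",
        [
            (0, 5, False, "0-5"),
            (5, 10, False, "5-10"),
            (10, 20, False, "10-20"),
            (20, 40, False, "20-40"),
            (40, 90, False, ">40"),
            (40, 70, False, ">40"),
            (-5, 0, True, "OL"),
        ],
    )
    def test_assignment(self, top, bottom, organic, expected):
        assert assign_depth_bin(top, bottom, organic) == expected

    def test_unknown_interval_rejected(self):
        with pytest.raises(ValueError):
            assign_depth_bin(3, 12, False)

    def test_midpoints(self):
        assert depth_midpoint(10, 20) == pytest.approx(15.0)
        assert depth_midpoint(40, float("nan")) == pytest.approx(65.0)
        assert math.isnan(depth_midpoint(-5, 0, organic_layer=True))


class TestLanduseSummary:
    def _fits(self):
        rows = []
        for i, v in enumerate((2.0, 4.0, 6.0)):
            rows.append(
                {
                    "site": f"s{i}",
                    "land_use": "cropland",
                    "depth_top_cm": 0.0,
                    "depth_bottom_cm": 5.0,
                    "organic_layer": False,
                    "sa_median_yr": v,
                }
            )
        rows.append(
            {
                "site": "s9",
                "land_use": "forest",
                "depth_top_cm": 5.0,
                "depth_bottom_cm": 10.0,
                "organic_layer": False,
                "sa_median_yr": 123.0,
            }
        )
        return pd.DataFrame(rows)

    def test_mean_and_sample_sd(self):
        out = landuse_summary(self._fits(), value_cols=["sa_median_yr"])
        row = out[(out.land_use == "cropland") & (out.depth_bin == "0-5")].iloc[0]
        assert row["sa_median_yr_mean"] == pytest.approx(4.0)
        assert row["sa_median_yr_sd"] == pytest.approx(2.0)

    def test_singleton_cell_has_missing_sd(self):
        out = landuse_summary(self._fits(), value_cols=["sa_median_yr"])
        row = out[(out.land_use == "forest")].iloc[0]
        assert row["n"] == 1
        assert math.isnan(row["sa_median_yr_sd"])

    def test_empty_cells_absent(self):
        out = landuse_summary(self._fits(), value_cols=["sa_median_yr"])
        assert len(out) == 2  # only populated land-use x depth cells appear

    def test_unknown_interval_lists_rows(self):
        bad = self._fits()
        bad.loc[0, "depth_bottom_cm"] = 7.0
        with pytest.raises(ValueError, match="unknown depth interval"):
            landuse_summary(bad, value_cols=["sa_median_yr"])
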