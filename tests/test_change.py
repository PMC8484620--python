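"""Change arithmetic, change maps, grids, cross-tabulation and
regional reports."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

import fragtrack as ft
from fragtrack.change import LOSS, GAIN, STABLE_FOREST, STABLE_NONFOREST
from fragtrack.datasets import (
    CTML_YEARS,
    ctml_class_areas,
    ctml_forest_areas,
)
from fragtrack.landscape import FOREST


def _landscape(values, pixel_size=30.0, year=2000):
    values = np.asarray(values, dtype=np.int8)
    return ft.BinaryLandscape(values, pixel_size=pixel_size,
                              origin=(0.0, values.shape[0] * pixel_size), epoch_year=year)


class TestScalarArithmetic:
    def test_published_total_loss_percentage(self):
        """24315.56 → 19069.14 km² is a 21.58 % loss."""
        assert ft.percent_change(24315.56, 19069.14) == pytest.approx(-21.58, abs=0.005)

    def test_published_core1_expansion(self):
        assert ft.percent_change(42.18, 509.25) == pytest.approx(1107.33, abs=0.005)

    def test_no_change_is_zero(self):
        for x in (0.5, 42.18, 24315.56):
            assert ft.percent_change(x, x) == 0.0
            assert ft.annual_rate(x, x, 1930, 2020) == 0.0

    def test_published_overall_annual_rate(self):
        """90-year compound rate of the total series is −0.27 %/yr."""
        r = ft.annual_rate(24315.56, 19069.14, 1930, 2020)
        assert r == pytest.approx(-0.27, abs=0.005)

    def test_published_early_period_rate_is_steeper(self):
        r = ft.annual_rate(24315.56, 21320.92, 1930, 1975)
        assert r == pytest.approx(-0.29, abs=0.005)

    def test_analytic_doubling(self):
        assert ft.annual_rate(50, 100, 0, 10) == pytest.approx(100 * math.log(2) / 10)

    def test_zero_final_area_diverges_with_warning(self):
        with pytest.warns(UserWarning, match="-inf"):
            assert ft.annual_rate(10.0, 0.0, 2000, 2020) == -math.inf

    def test_zero_initial_area_is_missing(self):
        with pytest.warns(UserWarning):
            assert math.isnan(ft.percent_change(0.0, 5.0))

    @given(a1=st.floats(0.01, 1e6), a2=st.floats(0.01, 1e6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_percent_and_rate_agree_in_sign(self, a1, a2):
        pc = ft.percent_change(a1, a2)
        r = ft.annual_rate(a1, a2, 0, 10)
        assert pc == 0 or r == 0 or (pc > 0) == (r > 0)

    @pytest.mark.parametrize("r", [-1.0, -0.27, 0.5])
    def test_rate_percent_consistency(self, r):
        """a2 = a1·e^{rΔt/100} round-trips through both measures."""
        a1, dt = 1000.0, 45
        a2 = a1 * math.exp(r * dt / 100)
        assert ft.annual_rate(a1, a2, 0, dt) == pytest.approx(r)
        assert ft.percent_change(a1, a2) == pytest.approx(100 * (math.exp(r * dt / 100) - 1))


class TestPublishedTables:
    """The change arithmetic reproduces the published CTML tables."""

    @pytest.mark.parametrize("region,rates", [
        ("Eastern", [-0.27, -0.31, -0.32, -0.29]),
        ("Central", [-0.09, -0.24, -0.19, -0.16]),
        ("Western", [-0.40, -0.30, -0.19, -0.33]),
        ("Far-western", [-0.33, -0.17, -0.30, -0.28]),
        ("Total", [-0.29, -0.25, -0.25, -0.27]),
    ])
    def test_regional_annual_rates_at_2dp(self, region, rates):
        areas = ctml_forest_areas().loc[region]
        pairs = [(1930, 1975), (1975, 2000), (2000, 2020), (1930, 2020)]
        for (y1, y2), expected in zip(pairs, rates):
            r = ft.annual_rate(areas[y1], areas[y2], y1, y2)
            assert r == pytest.approx(expected, abs=0.005), (region, y1, y2)

    @pytest.mark.parametrize("region,pcts", [
        ("Eastern", [-11.35, -7.42, -22.99]),
        ("Central", [-4.03, -5.87, -13.03]),
        ("Western", [-16.60, -7.23, -25.51]),
        ("Far-western", [-13.66, -4.22, -22.06]),
        ("Total", [-12.32, -5.95, -21.58]),
    ])
    def test_regional_percent_changes_at_2dp(self, region, pcts):
        areas = ctml_forest_areas().loc[region]
        pairs = [(1930, 1975), (1975, 2000), (1930, 2020)]
        for (y1, y2), expected in zip(pairs, pcts):
            assert ft.percent_change(areas[y1], areas[y2]) == pytest.approx(
                expected, abs=0.005), (region, y1, y2)

    @pytest.mark.parametrize("cls,pcts", [
        ("edge", [160.05, 3.02, 12.67, 201.84]),
        ("perforated", [None, -23.78, 18.39, None]),
        ("core1", [901.23, 12.31, 7.36, 1107.33]),
        ("core2", [219.23, 16.08, 13.57, 320.86]),
        ("core3", [-31.36, -6.25, -11.56, -43.08]),
    ])
    def test_fragmentation_class_percent_changes(self, cls, pcts):
        areas = ctml_class_areas().loc[cls]
        pairs = [(1930, 1975), (1975, 2000), (2000, 2020), (1930, 2020)]
        for (y1, y2), expected in zip(pairs, pcts):
            if expected is None:  # tiny 1930 denominators flagged in the source
                continue
            assert ft.percent_change(areas[y1], areas[y2]) == pytest.approx(
                expected, abs=0.005), (cls, y1, y2)

    def test_change_report_from_areas_layout(self):
        areas = ctml_forest_areas().loc["Total"].to_dict()
        report = ft.change_report_from_areas(areas)
        assert list(report["period"]) == ["1930-1975", "1975-2000", "2000-2020",
                                          "1930-2020"]
        total_row = report[report["period"] == "1930-2020"].iloc[0]
        assert total_row["percent_change"] == pytest.approx(-21.58, abs=0.005)
        assert total_row["annual_rate_pct"] == pytest.approx(-0.27, abs=0.005)


class TestChangeMap:
    def test_identity_has_no_change(self, random_landscape):
        a = random_landscape(seed=1)
        cm = ft.change_map(a, a.with_values(a.values, epoch_year=2020))
        assert cm.loss_area_km2 == 0 and cm.gain_area_km2 == 0

    def test_total_clearance(self, random_landscape):
        a = random_landscape(seed=2)
        b = a.with_values(np.zeros_like(a.values), epoch_year=2020)
        cm = ft.change_map(a, b)
        assert cm.loss_area_km2 == pytest.approx(a.forest_area_km2)

    def test_contingency_against_cellwise_tally(self, random_landscape):
        a = random_landscape(seed=3, p_forest=0.5)
        b = random_landscape(seed=4, p_forest=0.5)
        b = a.with_values(b.values, epoch_year=2020)
        cm = ft.change_map(a, b)
        f1, f2 = a.values == FOREST, b.values == FOREST
        assert (cm.values == LOSS).sum() == (f1 & ~f2).sum()
        assert (cm.values == GAIN).sum() == (~f1 & f2).sum()
        assert (cm.values == STABLE_FOREST).sum() == (f1 & f2).sum()
        assert (cm.values == STABLE_NONFOREST).sum() == (~f1 & ~f2).sum()
        # loss + stable forest = epoch-1 forest, exactly
        assert cm.loss_area_km2 + cm.area_km2(STABLE_FOREST) == pytest.approx(
            a.forest_area_km2)

    def test_misaligned_rasters_rejected(self, random_landscape):
        a = random_landscape(seed=1)
        b = random_landscape(rows=41, seed=1)
        with pytest.raises(ft.AlignmentError):
            ft.change_map(a, b)


class TestGridSummary:
    @staticmethod
    def _series(seed=0, rows=60, cols=60, rate=-1.0):
        cfg = ft.SimulationConfig(rows=rows, cols=cols, annual_rate=rate,
                                  epoch_years=(1930, 1975, 2020), seed=seed)
        return ft.simulate_series(cfg)

    def test_grid_additivity_per_epoch(self):
        series = self._series()
        grid = ft.make_grid(series.first, 450.0)
        df = ft.grid_change_summary(series, grid)
        for epoch in series:
            total = df[f"area_{epoch.epoch_year}_km2"].sum()
            assert total == pytest.approx(epoch.forest_area_km2, abs=1e-9)

    def test_uniform_clearance_categories(self, random_landscape):
        a = random_landscape(seed=5, p_forest=0.6)
        a = a.with_values(a.values, epoch_year=1930)
        b = a.with_values(np.zeros_like(a.values), epoch_year=2020)
        series = ft.LandscapeSeries((a, b))
        grid = ft.make_grid(a, 300.0)
        df = ft.grid_change_summary(series, grid)
        had_forest = df["area_1930_km2"] > 0
        assert (df.loc[had_forest, "category"] == "complete_loss").all()
        assert (df.loc[~had_forest, "category"] == "stable").all()

    def test_no_change_all_stable(self, random_landscape):
        a = random_landscape(seed=6)
        a = a.with_values(a.values, epoch_year=1930)
        b = a.with_values(a.values.copy(), epoch_year=2020)
        df = ft.grid_change_summary(ft.LandscapeSeries((a, b)),
                                    ft.make_grid(a, 300.0))
        assert (df["category"] == "stable").all()

    def test_complete_loss_subset_of_negative_change(self):
        series = self._series(seed=3, rate=-3.0)
        df = ft.grid_change_summary(series, ft.make_grid(series.first, 450.0))
        cl = df["category"] == "complete_loss"
        assert (df.loc[cl, "change_km2"] < 0).all() or cl.sum() == 0
        assert set(df["category"]) <= {"complete_loss", "deforested", "gain", "stable"}


class TestCrosstab:
    def test_identity_is_diagonal(self, clumped_landscape):
        ls = clumped_landscape(seed=2)
        m = ft.classify_fragmentation(ls)
        xt = ft.crosstab(m, m)
        off_diag = xt.to_numpy() - np.diag(np.diag(xt.to_numpy()))
        assert np.all(off_diag == 0)

    def test_marginals_reproduce_class_summaries(self):
        cfg = ft.SimulationConfig(rows=80, cols=80, annual_rate=-1.5,
                                  epoch_years=(1930, 2020), seed=4)
        series = ft.simulate_series(cfg)
        m1 = ft.classify_fragmentation(series.first)
        m2 = ft.classify_fragmentation(series.last)
        xt = ft.crosstab(m1, m2)
        t1, t2 = ft.class_area_summary(m1), ft.class_area_summary(m2)
        for cls in xt.index:
            assert xt.loc[cls].sum() == pytest.approx(t1.areas_km2[cls], abs=1e-9)
            assert xt[cls].sum() == pytest.approx(t2.areas_km2[cls], abs=1e-9)
        assert xt.to_numpy().sum() == pytest.approx(series.first.landscape_area_km2)

    def test_param_mismatch_rejected(self, clumped_landscape):
        ls = clumped_landscape(seed=2)
        m1 = ft.classify_fragmentation(ls, ft.FragParams(edge_width=100))
        m2 = ft.classify_fragmentation(ls, ft.FragParams(edge_width=50))
        with pytest.raises(ValueError, match="parameters"):
            ft.crosstab(m1, m2)


class TestPointsInLoss:
    def test_all_points_outside_rejected(self, random_landscape):
        a = random_landscape(seed=1)
        b = a.with_values(np.zeros_like(a.values), epoch_year=2020)
        cm = ft.change_map(a, b)
        pts = ft.PointSet(np.array([1e6]), np.array([1e6]))
        with pytest.raises(ValueError, match="extent"):
            ft.points_in_loss(pts, cm)

    def test_outside_points_excluded_but_reported(self, random_landscape):
        a = random_landscape(seed=2, p_forest=1.0)
        b = a.with_values(np.zeros_like(a.values), epoch_year=2020)
        cm = ft.change_map(a, b)  # everything is loss
        pts = ft.PointSet(np.array([15.0, 1e6]), np.array([15.0, 15.0]))
        frac, labels = ft.points_in_loss(pts, cm)
        assert frac == 1.0
        assert labels["change_class"].tolist() == ["loss", "outside_extent"]


class TestRegionalReport:
    @staticmethod
    def _two_region_setup(seed=0):
        cfg = ft.SimulationConfig(rows=60, cols=80, annual_rate=-1.0,
                                  epoch_years=(1930, 2020), seed=seed)
        series = ft.simulate_series(cfg)
        xmin, ymin, xmax, ymax = series.first.bounds
        mid = (xmin + xmax) / 2
        regions = [("west", box(xmin, ymin, mid, ymax)),
                   ("east", box(mid, ymin, xmax, ymax))]
        return series, regions

    def test_identity_series_has_zero_change(self, clumped_landscape):
        a = clumped_landscape(seed=3)
        a = a.with_values(a.values, epoch_year=1930)
        b = a.with_values(a.values.copy(), epoch_year=2020)
        series = ft.LandscapeSeries((a, b))
        xmin, ymin, xmax, ymax = a.bounds
        report = ft.regional_report(series, [("all", box(xmin, ymin, xmax, ymax))])
        assert (report.change["percent_change"].abs() < 1e-12).all()
        assert (report.change["annual_rate_pct"].abs() < 1e-12).all()

    def test_region_rows_sum_to_total(self):
        series, regions = self._two_region_setup()
        report = ft.regional_report(series, regions)
        fa = report.forest_area
        for y in series.years:
            assert fa.loc["Total", y] == pytest.approx(
                fa.loc["west", y] + fa.loc["east", y])
            assert fa.loc["Total", y] == pytest.approx(
                series[series.years.index(y)].forest_area_km2)
        assert fa.loc["Total", f"share_{series.years[0]}_pct"] == pytest.approx(100.0)

    def test_class_tables_conserve_forest_per_region(self):
        series, regions = self._two_region_setup(seed=5)
        report = ft.regional_report(series, regions)
        for y in series.years:
            region_sum = sum(report.class_area[name][y].sum()
                             for name in ("west", "east"))
            epoch = series[series.years.index(y)]
            assert region_sum == pytest.approx(epoch.forest_area_km2, abs=1e-9)
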