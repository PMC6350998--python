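"""Aggregate SST statistics and derived climate/hatchling predictors."""

import numpy as np
import pytest

from coldstun import covariates as cov
from coldstun.data_io import (
    ClimateIndexSeries,
    DailySstSeries,
    DataValidationError,
    HatchlingSeries,
)


def daily(values, start="2000-01-01", err=0.2):
    values = np.asarray(values, dtype=float)
    dates = np.arange(np.datetime64(start), np.datetime64(start) + values.size)
    return DailySstSeries(dates, values, np.full(values.size, err))


class TestAggregateSst:
    @pytest.mark.parametrize(
        "stat,expected",
        [
            ("min", 9.0),
            ("max", 12.0),
            ("mean", 10.5),
            ("days_below_10", 1.0),
            ("days_above_20", 0.0),
            ("sd", 1.2909944487358056),  # sample SD of 9,10,11,12
        ],
    )
    def test_known_values(self, stat, expected):
        sst = daily([9.0, 10.0, 11.0, 12.0])
        win = (np.datetime64("2000-01-01"), np.datetime64("2000-01-04"))
        assert cov.aggregate_sst(sst, win, stat) == pytest.approx(expected)

    def test_constant_series_degenerate_stats(self):
        sst = daily([7.0] * 5)
        win = (np.datetime64("2000-01-01"), np.datetime64("2000-01-05"))
        assert cov.aggregate_sst(sst, win, "sd") == 0.0
        assert (
            cov.aggregate_sst(sst, win, "min")
            == cov.aggregate_sst(sst, win, "max")
            == cov.aggregate_sst(sst, win, "mean")
            == 7.0
        )

    def test_thresholds_are_strict(self):
        sst = daily([10.0, 20.0])
        win = (np.datetime64("2000-01-01"), np.datetime64("2000-01-02"))
        assert cov.aggregate_sst(sst, win, "days_below_10") == 0
        assert cov.aggregate_sst(sst, win, "days_above_20") == 0

    def test_missing_day_is_hard_error(self):
        sst = daily([9.0, 10.0, 11.0])
        win = (np.datetime64("2000-01-01"), np.datetime64("2000-01-05"))
        with pytest.raises(DataValidationError):
            cov.aggregate_sst(sst, win, "mean")

    def test_matches_brute_force_on_random_windows(self):
        """Vectorized path equals a naive pure-python recomputation."""
        import statistics

        rng = np.random.default_rng(7)
        values = rng.normal(12.0, 5.0, 400)
        sst = daily(values)
        start = np.datetime64("2000-01-01")
        for _ in range(250):
            a = int(rng.integers(0, 390))
            b = int(rng.integers(a, min(a + 60, 399)))
            stat = cov.AGGREGATE_STATS[rng.integers(0, 6)]
            win = (start + a, start + b)
            got = cov.aggregate_sst(sst, win, stat)
            chunk = [float(v) for v in values[a : b + 1]]
            exp = {
                "mean": statistics.fmean(chunk),
                "max": max(chunk),
                "min": min(chunk),
                "sd": statistics.stdev(chunk) if len(chunk) > 1 else 0.0,
                "days_below_10": sum(v < 10 for v in chunk),
                "days_above_20": sum(v > 20 for v in chunk),
            }[stat]
            assert got == pytest.approx(exp, rel=1e-12, abs=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(10, 2, 50)
        dates = np.arange(np.datetime64("2000-01-01"), np.datetime64("2000-01-01") + 50)
        perm = rng.permutation(50)
        # a permuted-then-sorted container must give identical covariates
        s1 = daily(values)
        order = np.argsort(dates[perm])
        s2 = DailySstSeries(dates[perm][order], values[perm][order],
                            np.full(50, 0.2))
        win = (np.datetime64("2000-01-10"), np.datetime64("2000-02-05"))
        for stat in cov.AGGREGATE_STATS:
            assert cov.aggregate_sst(s1, win, stat) == cov.aggregate_sst(s2, win, stat)


class TestDerivedPredictors:
    def test_hatchling_lag_average(self):
        h = HatchlingSeries(np.arange(1996, 2001), [900, 600, 300, 0, 0])
        assert cov.hatchlings_lag_avg(h, 2000) == 600.0  # (300+600+900)/3
        h2 = HatchlingSeries(np.arange(1996, 2001), [4, 2, 1, 0, 0])
        assert cov.hatchlings_lag_avg(h2, 2000) == pytest.approx(7 / 3)

    def test_hatchling_missing_lag_year_errors(self):
        h = HatchlingSeries(np.arange(1998, 2001), [1, 2, 3])
        with pytest.raises(DataValidationError):
            cov.hatchlings_lag_avg(h, 2000)  # needs 1996

    def test_nao_summer_sum(self):
        idx = ClimateIndexSeries([2000] * 4, [6, 7, 8, 9], [0.1, -0.2, 0.3, 0.4])
        assert cov.nao_summer_sum(idx, 2000) == pytest.approx(0.6)

    def test_nao_summer_sum_missing_month_errors(self):
        idx = ClimateIndexSeries([2000] * 3, [6, 8, 9], [0.1, 0.3, 0.4])
        with pytest.raises(DataValidationError):
            cov.nao_summer_sum(idx, 2000)

    def test_annual_index_mean_with_lag(self):
        idx = ClimateIndexSeries([1998] * 12, range(1, 13), np.arange(1.0, 13.0))
        assert cov.annual_index_mean(idx, 2000, lag=2) == pytest.approx(6.5)
        with pytest.raises(DataValidationError):
            cov.annual_index_mean(idx, 2000, lag=1)


class TestBuildCovariateTable:
    def test_default_table_has_eleven_predictors(self, default_scenario):
        from coldstun.windows import WindowSpec

        sc = default_scenario
        w = {s: WindowSpec(77, 47) for s in cov.AGGREGATE_STATS}
        table = cov.build_covariate_table(
            sc.strandings, sc.sst, sc.hatchlings, sc.nao, sc.amo, w
        )
        assert len(table.columns) == 11
        assert table.frame.notna().all().all()
        assert table.error_specs["sst_min"].kind == "heteroscedastic"
        assert table.error_specs["hatchlings_lag_avg"].kind == "homoscedastic"

    def test_restricted_column_config(self, default_scenario):
        from coldstun.windows import WindowSpec

        sc = default_scenario
        w = {s: WindowSpec(77, 47) for s in cov.AGGREGATE_STATS}
        table = cov.build_covariate_table(
            sc.strandings, sc.sst, sc.hatchlings, sc.nao, sc.amo, w,
            columns=("sst_min", "hatchlings_lag_avg"),
        )
        assert table.columns == ["sst_min", "hatchlings_lag_avg"]

    def test_years_with_missing_lags_are_dropped_with_warning(self, default_scenario, caplog):
        from coldstun.windows import WindowSpec

        sc = default_scenario
        # hatchling series starting too late: the first stranding years lack lag-4 data
        short = HatchlingSeries(
            sc.hatchlings.years[15:], sc.hatchlings.hatchlings[15:]
        )
        w = {s: WindowSpec(77, 47) for s in cov.AGGREGATE_STATS}
        with caplog.at_level("WARNING"):
            table = cov.build_covariate_table(
                sc.strandings, sc.sst, short, sc.nao, sc.amo, w
            )
        assert len(table.years) < len(sc.strandings)
        assert any("excluding year" in r.message for r in caplog.records)

    def test_error_spec_sidecar_frame(self, default_scenario):
        from coldstun.windows import WindowSpec

        sc = default_scenario
        w = {s: WindowSpec(77, 47) for s in cov.AGGREGATE_STATS}
        table = cov.build_covariate_table(
            sc.strandings, sc.sst, sc.hatchlings, sc.nao, sc.amo, w
        )
        side = table.error_spec_frame()
        assert set(side["error_type"]) <= {"heteroscedastic", "homoscedastic", "none"}
        assert (side.loc[side["column"] == "sst_min", "error_type"] == "heteroscedastic").all()
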