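"""Per-year candidate predictors derived from SST, climate indices and hatchlings.

Six aggregate statistics summarize the daily-mean SST inside a climate time
window: mean, maximum, minimum, sample standard deviation, number of days
with daily mean below 10 °C (the temperature at which cold-stun symptoms
set in) and number of days above 20 °C (uncharacteristically warm water).
Threshold day counts use strict inequalities; the SD uses the n−1
denominator.

The remaining candidates are the June–September sum of monthly NAO values,
the annual-mean NAO lagged two years (a Gulf Stream position proxy), the
annual-mean AMO plus its 1–3-year lag average, and the hatchlings released
2–4 years earlier, averaged — the cohort ages of the juveniles that strand.
The default table therefore holds 11 predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_model import MeasurementErrorSpec, derive_homoscedastic_sd
from .data_io import (
    ClimateIndexSeries,
    DailySstSeries,
    DataValidationError,
    HatchlingSeries,
    StrandingSeries,
)

__all__ = [
    "AGGREGATE_STATS",
    "CovariateTable",
    "aggregate_sst",
    "hatchlings_lag_avg",
    "nao_summer_sum",
    "annual_index_mean",
    "build_covariate_table",
]

logger = logging.getLogger(__name__)

#: the six aggregate SST statistics
AGGREGATE_STATS = ("mean", "max", "min", "sd", "days_below_10", "days_above_20")

HATCHLING_LAGS = (2, 3, 4)
SUMMER_MONTHS = (6, 7, 8, 9)
AMO_LAGS = (1, 2, 3)


def _window_values(sst: DailySstSeries, start, end, what: str = "sst") -> np.ndarray:
    """Daily values for every day in [start, end]; any missing day is fatal."""
    start = np.datetime64(start, "D")
    end = np.datetime64(end, "D")
    if end < start:
        raise ValueError(f"window end {end} precedes start {start}")
    lo = np.searchsorted(sst.dates, start)
    hi = np.searchsorted(sst.dates, end, side="right")
    expected = int((end - start).astype(int)) + 1
    got = sst.dates[lo:hi]
    if got.size != expected:
        missing = np.setdiff1d(np.arange(start, end + 1), got)
        raise DataValidationError(
            f"daily SST missing inside window {start}..{end}: first missing {missing[:3]}"
        )
    return (sst.sst if what == "sst" else sst.sst_err_sd)[lo:hi]


def aggregate_sst(sst: DailySstSeries, window, stat: str) -> float:
    """One aggregate statistic of daily-mean SST over a date interval.

    ``window`` is an inclusive ``(start, end)`` pair of dates.  Every day of
    the interval must be present in the series.
    """
    if stat not in AGGREGATE_STATS:
        raise ValueError(f"unknown aggregate statistic {stat!r}")
    vals = _window_values(sst, window[0], window[1])
    return _apply_stat(vals, stat)


def _apply_stat(vals: np.ndarray, stat: str) -> float:
    if stat == "mean":
        return float(np.mean(vals))
    if stat == "max":
        return float(np.max(vals))
    if stat == "min":
        return float(np.min(vals))
    if stat == "sd":
        return float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if stat == "days_below_10":
        return float(np.sum(vals < 10.0))
    if stat == "days_above_20":
        return float(np.sum(vals > 20.0))
    raise ValueError(stat)


def window_error_sd(sst: DailySstSeries, window) -> float:
    """Mean per-day measurement SD over a window.

    The count model consumes one error SD per windowed observation, so the
    per-day SDs are aggregated by their mean.
    """
    return float(np.mean(_window_values(sst, window[0], window[1], "err")))


def hatchlings_lag_avg(h: HatchlingSeries, year: int) -> float:
    """Mean of hatchlings released 2, 3 and 4 years before ``year``."""
    return float(np.mean([h.value(year - lag) for lag in HATCHLING_LAGS]))


def nao_summer_sum(nao: ClimateIndexSeries, year: int) -> float:
    """Sum of the four monthly NAO values June–September of ``year``."""
    return float(np.sum(nao.monthly_values(year, SUMMER_MONTHS)))


def annual_index_mean(idx: ClimateIndexSeries, year: int, lag: int = 0) -> float:
    """Mean of the 12 monthly values of ``year − lag``."""
    return float(np.mean(idx.monthly_values(year - lag)))


DEFAULT_COLUMNS = (
    "sst_mean",
    "sst_max",
    "sst_min",
    "sst_sd",
    "sst_days_below_10",
    "sst_days_above_20",
    "nao_summer_sum",
    "nao_lag2",
    "amo_annual",
    "amo_lag_avg",
    "hatchlings_lag_avg",
)

SST_COLUMN_OF_STAT = {
    "mean": "sst_mean",
    "max": "sst_max",
    "min": "sst_min",
    "sd": "sst_sd",
    "days_below_10": "sst_days_below_10",
    "days_above_20": "sst_days_above_20",
}


@dataclass
class CovariateTable:
    """Per-year candidate predictors with attached measurement-error specs."""

    frame: pd.DataFrame  # index: year; one column per predictor
    error_specs: dict = field(default_factory=dict)  # column -> MeasurementErrorSpec

    def __post_init__(self):
        if self.frame.isna().any().any():
            raise DataValidationError("covariate table has missing cells")

    @property
    def years(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def columns(self) -> list:
        return list(self.frame.columns)

    def error_spec_frame(self) -> pd.DataFrame:
        """Sidecar error-spec table (column, error_type, sds)."""
        rows = []
        for col in self.frame.columns:
            spec = self.error_specs.get(col, MeasurementErrorSpec("none"))
            sds = "" if spec.kind == "none" else ";".join(
                f"{s:.10g}" for s in np.atleast_1d(spec.sds)
            )
            rows.append({"column": col, "error_type": spec.kind, "sds": sds})
        return pd.DataFrame(rows)


def build_covariate_table(
    strandings: StrandingSeries,
    sst: DailySstSeries,
    hatchlings: HatchlingSeries,
    nao: ClimateIndexSeries,
    amo: ClimateIndexSeries,
    window_results,
    columns=DEFAULT_COLUMNS,
) -> CovariateTable:
    """Assemble the candidate-predictor table for the modelled years.

    ``window_results`` maps each aggregate statistic to its best
    :class:`~coldstun.windows.WindowResult` (or WindowSpec), so every SST
    column is evaluated over its own optimal window.  The SST-minimum
    column carries per-year heteroscedastic error SDs (window-mean of the
    daily SDs); the hatchling column carries the constant SD derived from
    the last decade of releases.  Years whose lagged inputs are missing are
    excluded with a logged warning.
    """
    from .windows import WindowResult

    wmap = {}
    for stat, res in dict(window_results).items():
        wmap[stat] = res.best if isinstance(res, WindowResult) else res

    columns = list(columns)
    rows, kept_years, sst_min_sds = [], [], []
    for year, _ in zip(strandings.years, strandings.counts):
        row = {}
        try:
            for stat, col in SST_COLUMN_OF_STAT.items():
                if col not in columns:
                    continue
                win = wmap[stat].date_interval(int(year))
                row[col] = aggregate_sst(sst, win, stat)
            if "nao_summer_sum" in columns:
                row["nao_summer_sum"] = nao_summer_sum(nao, int(year))
            if "nao_lag2" in columns:
                row["nao_lag2"] = annual_index_mean(nao, int(year), lag=2)
            if "amo_annual" in columns:
                row["amo_annual"] = annual_index_mean(amo, int(year), lag=0)
            if "amo_lag_avg" in columns:
                row["amo_lag_avg"] = float(
                    np.mean([annual_index_mean(amo, int(year), lag=l) for l in AMO_LAGS])
                )
            if "hatchlings_lag_avg" in columns:
                row["hatchlings_lag_avg"] = hatchlings_lag_avg(hatchlings, int(year))
            if "sst_min" in columns:
                sst_min_sds.append(window_error_sd(sst, wmap["min"].date_interval(int(year))))
        except DataValidationError as exc:
            logger.warning("excluding year %d from covariate table: %s", year, exc)
            continue
        rows.append(row)
        kept_years.append(int(year))

    if not rows:
        raise DataValidationError("no year has complete covariate data")
    frame = pd.DataFrame(rows, index=pd.Index(kept_years, name="year"))[columns]

    specs = {}
    if "sst_min" in columns:
        specs["sst_min"] = MeasurementErrorSpec("heteroscedastic", np.asarray(sst_min_sds))
    if "hatchlings_lag_avg" in columns:
        sd = derive_homoscedastic_sd(hatchlings)
        if sd > 0:
            specs["hatchlings_lag_avg"] = MeasurementErrorSpec("homoscedastic", sd)
        else:
            logger.warning("last-decade hatchling SD is 0; no error spec attached")
    return CovariateTable(frame=frame, error_specs=specs)
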