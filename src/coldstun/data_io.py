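"""Readers, writers and validated containers for the four tabular inputs.

The pipeline consumes four delimited tables:

* annual cold-stun stranding counts (the response),
* annual hatchlings released at the Tamaulipas index beaches,
* daily regional-mean sea-surface temperature (SST) with per-day
  measurement SDs,
* monthly climate indices (NAO, AMO).

All tables are comma-delimited with one header row; column matching is
case-insensitive by name, never by position, so minor header variants in
supplementary files are tolerated.  Lines starting with ``#`` are comments.
Missing daily SST values are never imputed — downstream window statistics
fail loudly when a requested day is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StrandingSeries",
    "HatchlingSeries",
    "DailySstSeries",
    "ClimateIndexSeries",
    "read_strandings",
    "read_hatchlings",
    "read_daily_sst",
    "read_monthly_index",
    "write_strandings",
    "write_hatchlings",
    "write_daily_sst",
    "write_monthly_index",
    "packaged_strandings_path",
    "packaged_hatchlings_path",
]


class DataValidationError(ValueError):
    """An input table violates a structural invariant."""


def _as_int_array(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        flo = np.asarray(arr, dtype=float)
        if np.any(~np.isfinite(flo)) or np.any(flo != np.round(flo)):
            raise DataValidationError(f"{what} must be integers, got {arr.dtype}")
        arr = flo.astype(np.int64)
    return arr.astype(np.int64)


@dataclass(frozen=True)
class StrandingSeries:
    """Annual cold-stun stranding counts, contiguous in year.

    ``years`` are the calendar years labelling each stranding season (a
    season spans October–January but is labelled by its starting year).
    """

    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        years = _as_int_array(self.years, "years")
        counts = _as_int_array(self.counts, "counts")
        if years.size == 0:
            raise DataValidationError("stranding series is empty")
        if years.size != counts.size:
            raise DataValidationError("years and counts differ in length")
        if np.any(np.diff(years) <= 0):
            raise DataValidationError("years must be strictly increasing")
        if np.any(np.diff(years) != 1):
            raise DataValidationError("stranding years must be gap-free")
        if np.any(counts < 0):
            raise DataValidationError("counts must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return int(self.years.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "count": self.counts})


@dataclass(frozen=True)
class HatchlingSeries:
    """Annual number of hatchlings released, strictly increasing in year."""

    years: np.ndarray
    hatchlings: np.ndarray

    def __post_init__(self):
        years = _as_int_array(self.years, "years")
        h = _as_int_array(self.hatchlings, "hatchlings")
        if years.size == 0:
            raise DataValidationError("hatchling series is empty")
        if years.size != h.size:
            raise DataValidationError("years and hatchlings differ in length")
        if np.any(np.diff(years) <= 0):
            raise DataValidationError("years must be strictly increasing")
        if np.any(h < 0):
            raise DataValidationError("hatchlings must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "hatchlings", h)

    def __len__(self) -> int:
        return int(self.years.size)

    def value(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= self.years.size or self.years[idx] != year:
            raise DataValidationError(f"hatchling year {year} not in series")
        return int(self.hatchlings[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "hatchlings": self.hatchlings})


@dataclass(frozen=True)
class DailySstSeries:
    """Dated regional daily-mean SSTs with per-day measurement SDs."""

    dates: np.ndarray  # datetime64[D], strictly increasing
    sst: np.ndarray  # °C
    sst_err_sd: np.ndarray  # °C, > 0

    def __post_init__(self):
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        sst = np.asarray(self.sst, dtype=float)
        err = np.asarray(self.sst_err_sd, dtype=float)
        if dates.size == 0:
            raise DataValidationError("daily SST series is empty")
        if not (dates.size == sst.size == err.size):
            raise DataValidationError("SST fields differ in length")
        if np.any(np.diff(dates).astype(int) <= 0):
            raise DataValidationError("dates must be strictly increasing (no duplicates)")
        if np.any(~np.isfinite(sst)):
            raise DataValidationError("non-finite SST value")
        if np.any(~(err > 0)):
            raise DataValidationError("sst_err_sd must be > 0")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "sst", sst)
        object.__setattr__(self, "sst_err_sd", err)

    def __len__(self) -> int:
        return int(self.dates.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "sst": self.sst, "sst_err_sd": self.sst_err_sd}
        )


@dataclass(frozen=True)
class ClimateIndexSeries:
    """Monthly climate index values keyed by unique (year, month)."""

    years: np.ndarray
    months: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        years = _as_int_array(self.years, "years")
        months = _as_int_array(self.months, "months")
        values = np.asarray(self.values, dtype=float)
        if years.size == 0:
            raise DataValidationError("climate index series is empty")
        if not (years.size == months.size == values.size):
            raise DataValidationError("index fields differ in length")
        if np.any((months < 1) | (months > 12)):
            raise DataValidationError("months must lie in 1..12")
        key = years * 12 + (months - 1)
        order = np.argsort(key, kind="stable")
        if np.unique(key).size != key.size:
            raise DataValidationError("duplicate (year, month) entry")
        object.__setattr__(self, "years", years[order])
        object.__setattr__(self, "months", months[order])
        object.__setattr__(self, "values", values[order])

    def __len__(self) -> int:
        return int(self.years.size)

    def monthly_values(self, year: int, months=None) -> np.ndarray:
        """Values for the requested months of one year; error if any missing."""
        months = range(1, 13) if months is None else months
        key = self.years * 12 + (self.months - 1)
        out = []
        for m in months:
            k = year * 12 + (m - 1)
            idx = np.searchsorted(key, k)
            if idx >= key.size or key[idx] != k:
                raise DataValidationError(f"index value missing for {year}-{m:02d}")
            out.append(self.values[idx])
        return np.asarray(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "month": self.months, "value": self.values}
        )


# ---------------------------------------------------------------------------
# CSV plumbing


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                     float_precision="round_trip")
    if df.empty:
        raise DataValidationError(f"{path} contains no data rows")
    lower = {str(c).strip().lower(): c for c in df.columns}
    cols = {}
    for name in required:
        if name not in lower:
            raise DataValidationError(f"{path} lacks a '{name}' column (found {list(df.columns)})")
        cols[name] = lower[name]
    return df.rename(columns={v: k for k, v in cols.items()})[list(required)]


def read_strandings(path, year_range: tuple[int, int] | None = None) -> StrandingSeries:
    """Read annual stranding counts, optionally restricted to an inclusive year range.

    A year missing inside ``year_range`` is a hard error (the response must
    be gap-free); non-integer counts are a hard error.
    """
    df = _read_table(path, ("year", "count"))
    years = _as_int_array(df["year"].to_numpy(), "year")
    counts = _as_int_array(df["count"].to_numpy(), "count")
    if year_range is not None:
        lo, hi = int(year_range[0]), int(year_range[1])
        keep = (years >= lo) & (years <= hi)
        years, counts = years[keep], counts[keep]
        expected = np.arange(lo, hi + 1)
        if years.size != expected.size or np.any(np.sort(years) != expected):
            missing = sorted(set(expected.tolist()) - set(years.tolist()))
            if missing:
                raise DataValidationError(f"years missing inside range: {missing}")
            raise DataValidationError("duplicate years inside range")
    order = np.argsort(years, kind="stable")
    return StrandingSeries(years=years[order], counts=counts[order])


def read_hatchlings(path) -> HatchlingSeries:
    df = _read_table(path, ("year", "hatchlings"))
    years = _as_int_array(df["year"].to_numpy(), "year")
    h = _as_int_array(df["hatchlings"].to_numpy(), "hatchlings")
    if np.unique(years).size != years.size:
        raise DataValidationError("duplicate hatchling year")
    order = np.argsort(years, kind="stable")
    return HatchlingSeries(years=years[order], hatchlings=h[order])


def read_daily_sst(path) -> DailySstSeries:
    df = _read_table(path, ("date", "sst", "sst_err_sd"))
    dates = pd.to_datetime(df["date"]).to_numpy().astype("datetime64[D]")
    order = np.argsort(dates, kind="stable")
    return DailySstSeries(
        dates=dates[order],
        sst=df["sst"].to_numpy(float)[order],
        sst_err_sd=df["sst_err_sd"].to_numpy(float)[order],
    )


def read_monthly_index(path) -> ClimateIndexSeries:
    df = _read_table(path, ("year", "month", "value"))
    return ClimateIndexSeries(
        years=df["year"].to_numpy(),
        months=df["month"].to_numpy(),
        values=df["value"].to_numpy(float),
    )


def write_strandings(series: StrandingSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_hatchlings(series: HatchlingSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_daily_sst(series: DailySstSeries, path) -> None:
    df = series.to_frame()
    df["date"] = df["date"].astype(str)
    df.to_csv(path, index=False)


def write_monthly_index(series: ClimateIndexSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged example tables (synthetic stand-ins for the supplementary data)


def packaged_strandings_path() -> Path:
    """Path of the packaged synthetic annual stranding-count table (1982–2016)."""
    return Path(resources.files("coldstun.data") / "s1_strandings_synthetic.csv")


def packaged_hatchlings_path() -> Path:
    """Path of the packaged synthetic hatchlings-released table (1966–2018)."""
    return Path(resources.files("coldstun.data") / "s2_hatchlings_synthetic.csv")
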