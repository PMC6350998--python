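"""Sliding climate-window search for each aggregate SST statistic.

A candidate window is a contiguous span of days before a reference date
(31 December of the stranding year by default), written as day offsets
``(open, close)`` with ``open ≥ close ≥ 0``.  For every window on a grid
the aggregate statistic is computed per year and scored with the
small-sample-corrected AIC (AICc) of a Gaussian linear model of
``log(count + 1)`` on the windowed covariate; the best window is the exact
grid minimizer.  Ties (within numerical tolerance) are broken toward the
shorter window, then the later close.

Reported windows are collapsed to half-month labels: a boundary day on the
1st–14th of a month is the "early" half, the 15th onward the "late" half.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .covariates import AGGREGATE_STATS, _window_values, _apply_stat
from .data_io import DailySstSeries, StrandingSeries

__all__ = [
    "WindowSpec",
    "WindowResult",
    "enumerate_windows",
    "score_window",
    "best_window",
    "half_month_label",
    "describe_window",
]

#: year used only to render half-month labels (non-leap)
_LABEL_YEAR = 2015
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class WindowSpec:
    """Day offsets before a month-day reference anchor; open ≥ close ≥ 0."""

    open: int
    close: int
    reference: tuple[int, int] = (12, 31)

    def __post_init__(self):
        if not (self.open >= self.close >= 0):
            raise ValueError(f"need open >= close >= 0, got ({self.open}, {self.close})")

    @property
    def length(self) -> int:
        return self.open - self.close + 1

    def date_interval(self, year: int) -> tuple[np.datetime64, np.datetime64]:
        """Inclusive (start, end) dates of this window anchored in ``year``."""
        m, d = self.reference
        ref = np.datetime64(f"{year:04d}-{m:02d}-{d:02d}", "D")
        return ref - np.timedelta64(self.open, "D"), ref - np.timedelta64(self.close, "D")


@dataclass(frozen=True)
class WindowResult:
    stat: str
    best: WindowSpec
    ic_best: float
    ic_null: float
    half_month_label: str


def enumerate_windows(max_open: int, min_length: int = 1, reference=(12, 31)) -> list[WindowSpec]:
    """All windows with ``max_open ≥ open ≥ close ≥ 0`` and length ≥ ``min_length``."""
    out = []
    for o in range(max_open + 1):
        for c in range(0, o - min_length + 2):
            if o - c + 1 >= min_length:
                out.append(WindowSpec(o, c, reference))
    return out


def _aicc_ols(y: np.ndarray, x: np.ndarray | None) -> float:
    """AICc of a Gaussian linear model (intercept + optional slope)."""
    n = y.size
    ybar = y - y.mean()
    if x is None:
        rss = float(ybar @ ybar)
        k = 2  # intercept + variance
    else:
        xbar = x - x.mean()
        sxx = float(xbar @ xbar)
        rss = float(ybar @ ybar)
        if sxx > 0:
            rss -= float(xbar @ ybar) ** 2 / sxx
        k = 3  # intercept + slope + variance
    rss = max(rss, 1e-300)
    if n - k - 1 <= 0:
        raise ValueError(f"too few observations (n={n}) for AICc with k={k}")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _response(y: StrandingSeries) -> np.ndarray:
    return np.log(np.asarray(y.counts, dtype=float) + 1.0)


def covariate_series(
    y_years: np.ndarray, sst: DailySstSeries, w: WindowSpec, stat: str
) -> np.ndarray:
    """The windowed statistic evaluated for every modelled year."""
    return np.array(
        [_apply_stat(_window_values(sst, *w.date_interval(int(t))), stat) for t in y_years]
    )


def score_window(y: StrandingSeries, sst: DailySstSeries, w: WindowSpec, stat: str) -> float:
    """AICc of ``log(count+1)`` regressed on the windowed statistic."""
    if stat not in AGGREGATE_STATS:
        raise ValueError(f"unknown aggregate statistic {stat!r}")
    x = covariate_series(y.years, sst, w, stat)
    return _aicc_ols(_response(y), x)


def null_score(y: StrandingSeries) -> float:
    """AICc of the intercept-only baseline."""
    return _aicc_ols(_response(y), None)


def _day_matrix(y: StrandingSeries, sst: DailySstSeries, max_open: int, reference):
    """(n_years, max_open+1) daily SSTs indexed by offset before the reference."""
    m, d = reference
    n = len(y)
    out = np.empty((n, max_open + 1))
    for i, year in enumerate(y.years):
        ref = np.datetime64(f"{year:04d}-{m:02d}-{d:02d}", "D")
        start = ref - np.timedelta64(max_open, "D")
        vals = _window_values(sst, start, ref)  # errors if any day missing
        out[i] = vals[::-1]  # column j = offset j before the reference
    return out


def _stat_over_grid(D: np.ndarray, grid: list[WindowSpec], stat: str) -> np.ndarray:
    """(n_windows, n_years) windowed statistics, grouped by window length."""
    n_years = D.shape[0]
    out = np.empty((len(grid), n_years))
    by_len: dict[int, list[int]] = {}
    for i, w in enumerate(grid):
        by_len.setdefault(w.length, []).append(i)
    for length, idxs in by_len.items():
        view = sliding_window_view(D, length, axis=1)  # (years, starts, length)
        if stat == "mean":
            red = view.mean(axis=-1)
        elif stat == "max":
            red = view.max(axis=-1)
        elif stat == "min":
            red = view.min(axis=-1)
        elif stat == "sd":
            red = view.std(axis=-1, ddof=1) if length > 1 else np.zeros(view.shape[:2])
        elif stat == "days_below_10":
            red = (view < 10.0).sum(axis=-1).astype(float)
        elif stat == "days_above_20":
            red = (view > 20.0).sum(axis=-1).astype(float)
        else:
            raise ValueError(stat)
        for i in idxs:
            out[i] = red[:, grid[i].close]
    return out


def _aicc_over_grid(resp: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized AICc of resp ~ X[i] for every row i."""
    n = resp.size
    yc = resp - resp.mean()
    syy = float(yc @ yc)
    xc = X - X.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxy = xc @ yc
    rss = syy - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss = np.maximum(rss, 1e-300)
    k = 3
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def best_window(
    y: StrandingSeries,
    sst: DailySstSeries,
    stat: str,
    grid: list[WindowSpec] | None = None,
    max_open: int = 365,
    min_length: int = 14,
) -> WindowResult:
    """Exhaustive AICc minimization over the window grid.

    The default grid spans every window up to a year before 31 December
    with at least 14 days, covering all seasonally plausible spans.
    """
    if stat not in AGGREGATE_STATS:
        raise ValueError(f"unknown aggregate statistic {stat!r}")
    if grid is None:
        grid = enumerate_windows(max_open, min_length)
    if not grid:
        raise ValueError("empty window grid")
    refs = {w.reference for w in grid}
    if len(refs) != 1:
        raise ValueError("mixed reference anchors in grid")
    reference = refs.pop()
    grid_max = max(w.open for w in grid)

    D = _day_matrix(y, sst, grid_max, reference)
    X = _stat_over_grid(D, grid, stat)
    scores = _aicc_over_grid(_response(y), X)

    near = np.flatnonzero(scores <= scores.min() + _TIE_TOL)
    best_i = min(near, key=lambda i: (grid[i].length, grid[i].close, grid[i].open))
    best = grid[best_i]
    ic_best = score_window(y, sst, best, stat)  # exact recomputation
    return WindowResult(
        stat=stat,
        best=best,
        ic_best=ic_best,
        ic_null=null_score(y),
        half_month_label=describe_window(best),
    )


def half_month_label(day_of_month: int) -> str:
    """'early' for days 1–14, 'late' for day 15 onward."""
    if not 1 <= int(day_of_month) <= 31:
        raise ValueError(f"day of month out of range: {day_of_month}")
    return "early" if int(day_of_month) <= 14 else "late"


def describe_window(w: WindowSpec) -> str:
    """Half-month text such as 'late October thru early November'."""
    start, end = w.date_interval(_LABEL_YEAR)

    def part(d: np.datetime64) -> str:
        ts = d.astype("datetime64[D]").item()
        return f"{half_month_label(ts.day)} {calendar.month_name[ts.month]}"
    a, b = part(start), part(end)
    return a if a == b else f"{a} thru {b}"
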