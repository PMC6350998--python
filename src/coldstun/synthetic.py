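"""Synthetic data generator with known ground truth.

Emulates the structure of the real inputs so every pipeline stage is
testable offline: a daily regional-mean SST series with a seasonal cycle
(annual maximum in early August, so the late-October cooling limb behaves
like the Gulf of Maine), a linear warming trend, AR(1) day-to-day noise
and per-day measurement SDs drawn near 0.19 ± 0.02 °C; a saturating
(logistic) hatchling-release trend; and annual counts drawn from a
negative binomial whose log-mean is linear in a planted windowed SST
statistic (and optionally the lag-averaged hatchlings).

Measurement error enters at the level the count model consumes it: the
windowed statistic for year *t* is observed as the true value plus normal
noise with SD equal to the window-mean of the per-day SDs.  The generator
also produces simple AR(1) monthly NAO/AMO index series so the full
11-predictor candidate table can be assembled.

Every output is reproducible bit-for-bit from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import truncnorm

from .covariates import AGGREGATE_STATS, _apply_stat, _window_values
from .data_io import (
    ClimateIndexSeries,
    DailySstSeries,
    HatchlingSeries,
    StrandingSeries,
)
from .windows import WindowSpec

__all__ = ["ScenarioParams", "Scenario", "simulate_daily_sst",
           "simulate_hatchlings", "simulate_counts", "make_scenario"]


@dataclass(frozen=True)
class ScenarioParams:
    """Ground-truth parameters of one synthetic study.

    Defaults mirror the study conditions: 35 stranding seasons starting in
    1982, a Gulf-of-Maine-like seasonal cycle, a warming trend, SST
    measurement SDs near 0.19 ± 0.02 °C, a hatchling trend asymptoting in
    its final decade, and a strong positive effect (β1 = 1.2 per °C) of the
    planted windowed SST minimum (late October – mid November) on the
    NB-distributed counts.  β2 applies to the lag-averaged hatchlings in
    units of 10⁵ animals and defaults to 0 (no hatchling effect, as
    estimated for the real series).
    """

    seed: int = 0
    n_years: int = 35
    start_year: int = 1982
    sst_mean_annual: float = 11.0  # °C
    seasonal_amplitude: float = 8.0  # °C
    warming_slope: float = 0.03  # °C / year
    noise_sd: float = 0.8  # stationary SD of the AR(1) daily anomaly, °C
    noise_ar1: float = 0.7
    err_sd_mean: float = 0.19  # °C
    err_sd_sd: float = 0.02  # °C
    hatch_carrying_capacity: float = 6e5
    hatch_growth_rate: float = 0.18  # / year
    hatch_midpoint_year: float = 2000.0
    hatch_noise_sd: float = 0.08  # lognormal scale
    hatch_start_year: int = 1966
    beta0: float = -8.7
    beta1: float = 1.2  # per °C of the planted statistic
    beta2: float = 0.0  # per 1e5 lag-averaged hatchlings
    nb_size: float = 3.0
    planted_window: tuple[int, int] = (77, 47)  # Oct 15 – Nov 14 before Dec 31
    planted_stat: str = "min"

    def __post_init__(self):
        if not self.err_sd_mean > 0:
            raise ValueError("err_sd_mean must be > 0")
        if self.err_sd_sd < 0 or self.noise_sd < 0 or self.hatch_noise_sd < 0:
            raise ValueError("SD parameters must be non-negative")
        if not self.nb_size > 0:
            raise ValueError("nb_size must be > 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        o, c = self.planted_window
        if not (o >= c >= 0):
            raise ValueError("planted_window needs open >= close >= 0")
        if self.planted_stat not in AGGREGATE_STATS:
            raise ValueError(f"unknown planted_stat {self.planted_stat!r}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def planted_spec(self) -> WindowSpec:
        return WindowSpec(*self.planted_window)


_SEASONAL_PEAK_DOY = 217  # annual SST maximum in early August

# fixed spawn keys so each component has its own independent stream
_STREAMS = ("sst", "err_sd", "hatch", "counts", "x_obs", "nao", "amo")


def _rng(params: ScenarioParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _STREAMS.index(stream)])
    )


def simulate_daily_sst(params: ScenarioParams) -> DailySstSeries:
    """Daily SST = annual mean + warming trend + seasonal sinusoid + AR(1) noise.

    Per-day measurement SDs are drawn from a positive-truncated
    Normal(err_sd_mean, err_sd_sd²).  The series starts one year before the
    first stranding season so that every lookback window of the search grid
    (up to a full year before 31 December of the first season) is covered.
    """
    start = np.datetime64(f"{params.start_year - 1}-01-01", "D")
    end = np.datetime64(f"{params.start_year + params.n_years - 1}-12-31", "D")
    dates = np.arange(start, end + 1)
    n = dates.size
    t_years = (dates - np.datetime64(f"{params.start_year}-01-01", "D")).astype(float) / 365.25
    doy = (dates - dates.astype("datetime64[Y]").astype("datetime64[D]")).astype(float)
    seasonal = params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - _SEASONAL_PEAK_DOY) / 365.25
    )
    mean = params.sst_mean_annual + params.warming_slope * t_years + seasonal

    rng = _rng(params, "sst")
    noise = np.zeros(n)
    if params.noise_sd > 0:
        phi = params.noise_ar1
        innov_sd = params.noise_sd * np.sqrt(1.0 - phi**2)
        eps = rng.standard_normal(n)
        noise[0] = params.noise_sd * eps[0]
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + innov_sd * eps[i]

    rng_err = _rng(params, "err_sd")
    if params.err_sd_sd > 0:
        a = (0.0 - params.err_sd_mean) / params.err_sd_sd
        err = truncnorm.rvs(
            a, np.inf, loc=params.err_sd_mean, scale=params.err_sd_sd,
            size=n, random_state=rng_err,
        )
    else:
        err = np.full(n, params.err_sd_mean)
    return DailySstSeries(dates=dates, sst=mean + noise, sst_err_sd=err)


def simulate_hatchlings(params: ScenarioParams) -> HatchlingSeries:
    """Logistic-growth release trend with multiplicative lognormal noise.

    Runs from ``hatch_start_year`` through two years past the last
    stranding season, matching the span of the real release table relative
    to the modelled years.
    """
    years = np.arange(
        params.hatch_start_year, params.start_year + params.n_years + 2
    )
    mean = params.hatch_carrying_capacity / (
        1.0 + np.exp(-params.hatch_growth_rate * (years - params.hatch_midpoint_year))
    )
    rng = _rng(params, "hatch")
    if params.hatch_noise_sd > 0:
        s = params.hatch_noise_sd
        # mean-preserving lognormal factor
        factor = np.exp(rng.normal(0.0, s, years.size) - 0.5 * s**2)
    else:
        factor = np.ones(years.size)
    vals = np.maximum(np.round(mean * factor), 0).astype(np.int64)
    return HatchlingSeries(years=years, hatchlings=vals)


def _true_covariates(params, sst, hatch):
    """Planted windowed statistic (truth), window-mean error SD, hatch lag-avg."""
    from .covariates import hatchlings_lag_avg

    spec = params.planted_spec()
    x_true = np.empty(params.n_years)
    err_sd = np.empty(params.n_years)
    h = np.empty(params.n_years)
    for i, year in enumerate(params.years):
        start, endd = spec.date_interval(int(year))
        vals = _window_values(sst, start, endd)
        x_true[i] = _apply_stat(vals, params.planted_stat)
        err_sd[i] = float(np.mean(_window_values(sst, start, endd, "err")))
        h[i] = hatchlings_lag_avg(hatch, int(year))
    return x_true, err_sd, h


def simulate_counts(
    sst: DailySstSeries,
    hatch: HatchlingSeries,
    params: ScenarioParams,
    rng: np.random.Generator | None = None,
) -> StrandingSeries:
    """Annual counts y_t ~ NB(exp(β0 + β1 x_t + β2 h_t), k).

    ``x_t`` is the planted statistic over the planted window of the *true*
    daily series; ``h_t`` is the lag-2/3/4 hatchling average in units of
    10⁵ animals.
    """
    from .count_model import sample_nb

    rng = _rng(params, "counts") if rng is None else rng
    x_true, _, h = _true_covariates(params, sst, hatch)
    log_mu = params.beta0 + params.beta1 * x_true + params.beta2 * (h / 1e5)
    mu = np.exp(np.clip(log_mu, -30.0, 30.0))
    counts = sample_nb(rng, mu, params.nb_size)
    return StrandingSeries(years=params.years, counts=counts)


def _simulate_monthly_index(params: ScenarioParams, stream: str) -> ClimateIndexSeries:
    """AR(1) monthly index covering all lagged lookbacks of the modelled years."""
    first = params.start_year - 4
    last = params.start_year + params.n_years - 1
    n = (last - first + 1) * 12
    rng = _rng(params, stream)
    phi, sd = 0.3, 1.0
    vals = np.empty(n)
    eps = rng.standard_normal(n)
    vals[0] = sd * eps[0]
    innov = sd * np.sqrt(1 - phi**2)
    for i in range(1, n):
        vals[i] = phi * vals[i - 1] + innov * eps[i]
    years = np.repeat(np.arange(first, last + 1), 12)
    months = np.tile(np.arange(1, 13), last - first + 1)
    return ClimateIndexSeries(years=years, months=months, values=vals)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    params: ScenarioParams
    x_true: np.ndarray  # planted windowed statistic, per year (truth)
    x_obs: np.ndarray  # x_true + N(0, err_sd) — what the model observes
    err_sd: np.ndarray  # per-year window-mean measurement SD
    hatch_lag_avg: np.ndarray  # raw lag-2/3/4 average per year
    mu: np.ndarray  # true NB means


@dataclass
class Scenario:
    """Complete synthetic dataset bundle plus its ground truth."""

    strandings: StrandingSeries
    sst: DailySstSeries
    hatchlings: HatchlingSeries
    nao: ClimateIndexSeries
    amo: ClimateIndexSeries
    truth: GroundTruth

    def manifest(self) -> dict:
        d = asdict(self.truth.params)
        d["planted_window"] = list(d["planted_window"])
        return d


def make_scenario(params: ScenarioParams) -> Scenario:
    """Generate the full dataset bundle; identical params give identical bundles."""
    sst = simulate_daily_sst(params)
    hatch = simulate_hatchlings(params)
    counts = simulate_counts(sst, hatch, params)
    x_true, err_sd, h = _true_covariates(params, sst, hatch)
    rng = _rng(params, "x_obs")
    x_obs = x_true + rng.normal(0.0, 1.0, x_true.size) * err_sd
    log_mu = params.beta0 + params.beta1 * x_true + params.beta2 * (h / 1e5)
    truth = GroundTruth(
        params=params,
        x_true=x_true,
        x_obs=x_obs,
        err_sd=err_sd,
        hatch_lag_avg=h,
        mu=np.exp(np.clip(log_mu, -30.0, 30.0)),
    )
    return Scenario(
        strandings=counts,
        sst=sst,
        hatchlings=hatch,
        nao=_simulate_monthly_index(params, "nao"),
        amo=_simulate_monthly_index(params, "amo"),
        truth=truth,
    )
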