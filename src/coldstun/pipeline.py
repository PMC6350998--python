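"""End-to-end orchestration: covariates → windows → importance → model → forecast.

A run is fully specified by a :class:`RunConfig` (either four input-table
paths or a synthetic-scenario block, never both) plus a master seed.  Each
stage draws its randomness from a child seed derived from the master seed
and the stage name, so stages are reproducible in isolation and a repeated
run writes byte-identical outputs.

Outputs land in the run directory as CSV tables plus ``summary.json``
(selected window per statistic, importance rankings, top-two predictors,
final model covariates, DIC table, posterior summaries, overdispersion,
residual ACF, forecast table and the population-impact percentage).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import data_io
from .count_model import (
    ModelSpec,
    SamplerSettings,
    backward_select,
    dic,
    fit_nb_eiv,
    overdispersion_stat,
    residual_acf,
)
from .forecast import (
    PopulationAssumptions,
    fit_sst_trend,
    population_impact,
    predict_counts,
    project_sst,
)
from .importance import two_stage_select
from .synthetic import ScenarioParams, make_scenario
from .windows import best_window, enumerate_windows

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: SeedSequence(master, crc32(stage))."""
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), key]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 0
    outdir: str | Path = "run"
    # exactly one of these two blocks:
    inputs: dict | None = None  # strandings/hatchlings/sst/nao/amo paths (+year_range)
    scenario: ScenarioParams | dict | None = None
    # stage settings
    window_max_open: int = 365
    window_min_length: int = 14
    n_trees: int = 2000
    collinearity_threshold: float = 0.7
    sampler: SamplerSettings | dict = field(default_factory=SamplerSettings)
    forecast_horizon: int = 15
    forecast_error_sd: float = 0.5
    trend_last_n: int = 15
    population: PopulationAssumptions | dict = field(default_factory=PopulationAssumptions)

    def __post_init__(self):
        if (self.inputs is None) == (self.scenario is None):
            raise ValueError("config needs either input paths or a scenario block, not both")
        if isinstance(self.scenario, dict):
            sc = dict(self.scenario)
            if "planted_window" in sc:
                sc["planted_window"] = tuple(sc["planted_window"])
            self.scenario = ScenarioParams(**sc)
        if isinstance(self.sampler, dict):
            self.sampler = SamplerSettings(**self.sampler)
        if isinstance(self.population, dict):
            self.population = PopulationAssumptions(**self.population)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        sc = make_scenario(config.scenario)
        return sc.strandings, sc.sst, sc.hatchlings, sc.nao, sc.amo, sc
    paths = config.inputs
    try:
        strandings = data_io.read_strandings(
            paths["strandings"], year_range=tuple(paths["year_range"]) if "year_range" in paths else None
        )
        hatch = data_io.read_hatchlings(paths["hatchlings"])
        sst = data_io.read_daily_sst(paths["sst"])
        nao = data_io.read_monthly_index(paths["nao"])
        amo = data_io.read_monthly_index(paths["amo"])
    except (KeyError, FileNotFoundError, data_io.DataValidationError) as exc:
        raise RuntimeError(f"stage data_io failed: {exc}") from exc
    return strandings, sst, hatch, nao, amo, None


_STAGE_ORDER = ("windows", "covariates", "importance", "fit", "forecast")


def run_all(config: RunConfig, upto: str | None = None) -> dict:
    """Execute the stages in order and write their outputs; returns the summary.

    ``upto`` stops the run after the named stage (default: run everything).
    """
    if upto is not None and upto not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {upto!r}")
    stop_at = _STAGE_ORDER.index(upto) if upto else len(_STAGE_ORDER) - 1
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log_to(outdir / "run.log")

    strandings, sst, hatch, nao, amo, scenario = _load_inputs(config)
    summary: dict = {"seed": int(config.seed)}
    if scenario is not None:
        with open(outdir / "scenario_manifest.json", "w") as fh:
            json.dump(scenario.manifest(), fh, indent=2, default=str)
        data_io.write_strandings(strandings, outdir / "strandings.csv")
        data_io.write_hatchlings(hatch, outdir / "hatchlings.csv")
        data_io.write_daily_sst(sst, outdir / "daily_sst.csv")
        data_io.write_monthly_index(nao, outdir / "nao.csv")
        data_io.write_monthly_index(amo, outdir / "amo.csv")

    # --- stage: climate window search -------------------------------------
    logger.info("stage windows: grid max_open=%d min_length=%d",
                config.window_max_open, config.window_min_length)
    grid = enumerate_windows(config.window_max_open, config.window_min_length)
    window_results = {}
    wrows = []
    for stat in cov.AGGREGATE_STATS:
        try:
            res = best_window(strandings, sst, stat, grid=grid)
        except Exception as exc:
            raise RuntimeError(f"stage windows failed for stat {stat!r}: {exc}") from exc
        window_results[stat] = res
        wrows.append({"stat": stat, "open": res.best.open, "close": res.best.close,
                      "ic_best": res.ic_best, "ic_null": res.ic_null,
                      "label": res.half_month_label})
    window_table = pd.DataFrame(wrows)
    window_table.to_csv(outdir / "window_results.csv", index=False)
    summary["windows"] = window_table.to_dict(orient="records")
    if stop_at < 1:
        return _finish(summary, outdir)

    # --- stage: covariate table -------------------------------------------
    try:
        table = cov.build_covariate_table(strandings, sst, hatch, nao, amo, window_results)
    except Exception as exc:
        raise RuntimeError(f"stage covariates failed: {exc}") from exc
    table.frame.to_csv(outdir / "covariates.csv")
    table.error_spec_frame().to_csv(outdir / "covariate_error_specs.csv", index=False)
    modeled_years = table.years
    y_keep = np.isin(strandings.years, modeled_years)
    y = strandings.counts[y_keep]
    if stop_at < 2:
        return _finish(summary, outdir)

    # --- stage: permutation importance ------------------------------------
    try:
        sel = two_stage_select(
            y, table, n_trees=config.n_trees,
            threshold=config.collinearity_threshold,
            seed=stage_seed(config.seed, "importance"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage importance failed: {exc}") from exc
    sel.stage1.importances.rename("importance").to_csv(outdir / "importance_stage1.csv")
    sel.stage2.importances.rename("importance").to_csv(outdir / "importance_stage2.csv")
    summary["top_two"] = list(sel.top_two)
    summary["collinear_groups"] = sel.groups
    summary["stage2_ranking"] = sel.stage2.ranking
    logger.info("stage importance: top two = %s", sel.top_two)
    if stop_at < 3:
        return _finish(summary, outdir)

    # --- stage: count model with backward selection ------------------------
    spec = ModelSpec(
        covariates=tuple(sel.top_two),
        error={c: table.error_specs[c] for c in sel.top_two if c in table.error_specs},
    )
    try:
        result = backward_select(
            spec, y, table.frame, settings=config.sampler,
            seed=stage_seed(config.seed, "fit"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage count_model failed: {exc}") from exc
    fit = result.final_fit
    result.table.to_csv(outdir / "model_comparison.csv", index=False)
    fit.summary.to_csv(outdir / "posterior_summary.csv")
    acf = residual_acf(fit, max_lag=10)
    over = overdispersion_stat(fit)
    pd.DataFrame({"lag": np.arange(acf.size), "acf": acf}).to_csv(
        outdir / "residual_acf.csv", index=False
    )
    summary["final_covariates"] = list(result.final_spec.covariates)
    summary["dic_table"] = result.table.to_dict(orient="records")
    summary["dic_final"] = dic(fit)
    summary["overdispersion"] = over
    summary["residual_acf"] = acf.tolist()
    summary["posterior"] = {
        name: dict(row) for name, row in fit.summary.iterrows()
    }
    if stop_at < 4:
        return _finish(summary, outdir)

    # --- stage: forecast ----------------------------------------------------
    sst_col = next((c for c in result.final_spec.covariates if c.startswith("sst_")), None)
    if sst_col is None and "sst_min" in table.frame.columns:
        # the projection needs an SST-driven model; refit on the windowed minimum
        logger.info("final model lacks an SST term; refitting sst_min-only for the forecast")
        sst_col = "sst_min"
    forecast_spec = ModelSpec(
        covariates=(sst_col,),
        error={sst_col: table.error_specs[sst_col]} if sst_col in table.error_specs else {},
    )
    if list(result.final_spec.covariates) == [sst_col]:
        forecast_fit = fit
    else:
        forecast_fit = fit_nb_eiv(
            forecast_spec, y, table.frame, settings=config.sampler,
            seed=stage_seed(config.seed, "forecast_fit"),
        )
    try:
        trend = fit_sst_trend(modeled_years, table.frame[sst_col].to_numpy(),
                              last_n=config.trend_last_n)
        projected = project_sst(
            trend, start_year=int(modeled_years[-1]) + 1,
            horizon=config.forecast_horizon, error_sd=config.forecast_error_sd,
        )
        fc = predict_counts(forecast_fit, projected,
                            seed=stage_seed(config.seed, "forecast"))
    except Exception as exc:
        raise RuntimeError(f"stage forecast failed: {exc}") from exc
    fc.table.to_csv(outdir / "forecast.csv", index=False)
    impact = population_impact(config.population, float(fc.table["count_mean"].iloc[-1]))
    summary["trend"] = {"slope": trend.slope, "intercept": trend.intercept,
                        "anchor_year": trend.anchor_year}
    summary["forecast"] = fc.table.to_dict(orient="records")
    summary["population_impact_pct"] = impact
    logger.info("stage forecast: final-year predictive mean %.1f counts (%.2f%% of juveniles)",
                fc.table["count_mean"].iloc[-1], impact)

    if scenario is not None:
        truth = scenario.truth
        planted = truth.params.planted_spec()
        found = window_results[truth.params.planted_stat].best
        lo = max(found.close, planted.close)
        hi = min(found.open, planted.open)
        overlap = max(0, hi - lo + 1) / planted.length
        summary["truth"] = {
            "beta1": truth.params.beta1,
            "planted_stat": truth.params.planted_stat,
            "planted_window": [planted.open, planted.close],
            "window_overlap_frac": overlap,
        }

    return _finish(summary, outdir)


def _finish(summary: dict, outdir: Path) -> dict:
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _log_to(path: Path) -> None:
    root = logging.getLogger("coldstun")
    root.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler) and getattr(h, "baseFilename", None) == str(path)
        for h in root.handlers
    ):
        root.addHandler(logging.FileHandler(path))
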