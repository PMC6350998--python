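"""Shared fixtures: small synthetic bundles and the replicate simulation study.

The replicate study (100 seeded errors-in-variables fits on freshly drawn
scenarios) is session-scoped because several calibration checks — interval
coverage, bias, rank uniformity, overdispersion, DIC ordering — all read
from the same set of fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import coldstun as cs
from coldstun.count_model import (
    MeasurementErrorSpec,
    ModelSpec,
    SamplerSettings,
    dic,
    fit_nb_eiv,
    overdispersion_stat,
)

N_REPLICATES = 100
N_DIC_REPLICATES = 50  # intercept-only refits for the DIC comparison


def eiv_spec(err_sd: np.ndarray) -> ModelSpec:
    return ModelSpec(
        covariates=("sst_min",),
        error={"sst_min": MeasurementErrorSpec("heteroscedastic", err_sd)},
    )


@pytest.fixture(scope="session")
def default_scenario() -> cs.Scenario:
    return cs.make_scenario(cs.ScenarioParams(seed=1))


@pytest.fixture(scope="session")
def quick_fit(default_scenario):
    """One reduced-length EIV fit on the default scenario."""
    tr = default_scenario.truth
    X = pd.DataFrame({"sst_min": tr.x_obs})
    return fit_nb_eiv(
        eiv_spec(tr.err_sd), default_scenario.strandings, X,
        settings=SamplerSettings.reduced(), seed=7,
    )


@pytest.fixture(scope="session")
def eiv_replicates():
    """100 replicate EIV fits on independently drawn scenarios.

    Each record holds the posterior summary of the SST slope on the
    original scale, the rank of the true slope within the posterior draws,
    the overdispersion statistic, the fraction of true means inside the
    95% fitted band, and (for the first 50 replicates) the DIC of the SST
    model and of the intercept-only baseline.
    """
    truth_beta1 = 1.2
    rows = []
    for i in range(N_REPLICATES):
        params = cs.ScenarioParams(seed=1000 + i)
        sc = cs.make_scenario(params)
        tr = sc.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        fit = fit_nb_eiv(
            eiv_spec(tr.err_sd), sc.strandings, X,
            settings=SamplerSettings.reduced(), seed=i,
        )
        s = fit.summary.loc["beta_sst_min_orig"]
        draws = fit.draws["beta_sst_min_orig"]
        band = fit.fitted()
        inside = np.mean(
            (tr.mu >= band["mu_q025"].to_numpy()) & (tr.mu <= band["mu_q975"].to_numpy())
        )
        row = {
            "mean": s["mean"],
            "q025": s["q025"],
            "q975": s["q975"],
            "covered": bool(s["q025"] <= truth_beta1 <= s["q975"]),
            "rank_u": float(np.mean(draws < truth_beta1)),
            "overdispersion": overdispersion_stat(fit),
            "band_coverage": float(inside),
        }
        if i < N_DIC_REPLICATES:
            null_fit = fit_nb_eiv(
                ModelSpec(), sc.strandings, None,
                settings=SamplerSettings.reduced(), seed=i,
            )
            row["dic_sst"] = dic(fit)
            row["dic_null"] = dic(null_fit)
        rows.append(row)
    return pd.DataFrame(rows)
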