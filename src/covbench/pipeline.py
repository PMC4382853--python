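"""End-to-end orchestration: simulate -> preprocess -> covariates -> ST-GPR
-> benchmark, with the ground truth kept alongside for recovery checks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import benchmark as bm
from . import covariates as cm
from . import preprocess as pp
from . import stgpr
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "simulate_inputs"]


@dataclass
class PipelineResult:
    geo: syn.GeographyMap
    truth: syn.SyntheticTruth
    pop: syn.PopulationTable
    plan: list[syn.SurveySource]
    obs_raw: pd.DataFrame
    obs_clean: pd.DataFrame
    logit_obs: pd.DataFrame
    covariates: pd.DataFrame
    province_ind: pd.DataFrame
    stgpr: stgpr.STGPRResult
    report: bm.BenchmarkReport | None
    seed: int
    extras: dict = field(default_factory=dict)


def simulate_inputs(scenario: syn.Scenario | None = None, seed: int = 0,
                    n_provinces: int = 9, n_districts: int = 72,
                    n_split_parents: int = 15,
                    exact: bool = False,
                    plan: list[syn.SurveySource] | None = None,
                    irs_noise: float = 0.2):
    """Generate one complete synthetic study (inputs only)."""
    scenario = scenario or syn.default_scenario()
    geo = syn.generate_geography(n_provinces, n_districts, n_split_parents, seed)
    truth = syn.generate_truth(geo, scenario.years, scenario, seed)
    pop = syn.generate_population(
        geo, [scenario.years[0], 2000, scenario.years[1]],
        base=7_000_000, growth=0.028, seed=seed)
    plan = plan if plan is not None else syn.default_survey_plan(scenario)
    obs = syn.sample_observations(truth, plan, seed, exact=exact)
    cov_obs = syn.sample_covariate_observations(truth, plan, seed, exact=exact)
    hh = pp.interpolate_population(pop, truth.years)[
        ["district", "year", "households"]]
    admin_irs = None
    if "irs" in truth.indicators:
        admin_irs = syn.generate_admin_irs(
            truth, hh[hh["year"] >= 2005], 0.0 if exact else irs_noise, seed)
    return geo, truth, pop, plan, obs, cov_obs, admin_irs, hh


def run_pipeline(scenario: syn.Scenario | None = None, seed: int = 0,
                 n_draws: int = 1000,
                 n_provinces: int = 9, n_districts: int = 72,
                 n_split_parents: int = 15,
                 exact: bool = False,
                 plan: list[syn.SurveySource] | None = None,
                 pre_config: pp.PreprocessConfig | None = None,
                 st_config: stgpr.STConfig | None = None,
                 gpr_config: stgpr.GPRConfig | None = None,
                 cov_config: cm.CovariateModelConfig | None = None,
                 with_benchmark: bool = True,
                 recode_cutoff: int | None = 2000) -> PipelineResult:
    """Run the whole analysis on a synthetic study and return everything.

    ``exact=True`` replaces sampling noise by the true values (for identity
    checks); ``recode_cutoff`` aggregates observations before that year to
    the old geography before preprocessing re-harmonizes them (None skips).
    """
    scenario = scenario or syn.default_scenario()
    geo, truth, pop, plan, obs, cov_obs, admin_irs, hh = simulate_inputs(
        scenario, seed, n_provinces, n_districts, n_split_parents, exact, plan)
    obs_raw = obs
    if recode_cutoff is not None:
        obs = syn.recode_to_old_geography(obs, geo, recode_cutoff)

    pre_config = pre_config or pp.PreprocessConfig()
    obs_clean, logit_obs = pp.preprocess_observations(
        obs, geo, scenario.floor_years, truth.years,
        admin_irs=admin_irs, households=hh, config=pre_config)

    cov_config = cov_config or cm.CovariateModelConfig()
    cov_surface = cm.complete_covariates(cov_obs, geo.district_ids,
                                         truth.years, cov_config)
    prov_series = cm.province_indicator_series(logit_obs, geo, truth.years,
                                               cov_config)
    prov_ind = prov_series.rename(columns={"value": "value"})[
        ["indicator", "province", "year", "value"]]

    st_config = st_config or stgpr.STConfig()
    gpr_config = gpr_config or stgpr.GPRConfig()
    if gpr_config.seed == 0 and seed != 0:
        gpr_config = replace(gpr_config, seed=seed)
    if n_draws != gpr_config.n_draws:
        gpr_config = replace(gpr_config, n_draws=n_draws)
    result = stgpr.run_stgpr(logit_obs, cov_surface, prov_ind, geo,
                             truth.years, st_config, gpr_config)

    report = None
    if with_benchmark:
        spec = bm.CompositeSpec(components=tuple(
            c for c in bm.CompositeSpec().components
            if c in truth.indicators)) if len(truth.indicators) >= 10 else None
        if spec is not None and len(spec.components) == 10:
            report = bm.run_benchmark(result.cube, result.summary, pop,
                                      cov_surface, spec,
                                      years=scenario.years)
        else:
            logger.info("fewer than 10 basket components present; "
                        "skipping the composite report")
    return PipelineResult(geo, truth, pop, plan, obs_raw, obs_clean,
                          logit_obs, cov_surface, prov_ind, result, report,
                          seed)
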