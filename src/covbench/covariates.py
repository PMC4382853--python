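"""Two-step completion of sparse multi-source covariate series.

Step one is a linear mixed-effects model on a transformed scale (logit for
proportions, log for household size, identity for education): the fixed
effects are a natural cubic spline in year (one interior knot at 2000 by
default) and the random effects are a district-level intercept and slope.
Step two is a per-district Gaussian process regression that treats the
mixed-model prediction as the prior mean, so the completed series passes
near the data where data exist and relaxes to the regression trend where
they do not.

The same machinery, run at province level on logit-space indicator
observations, produces the province indicator series that the stage-1
district model uses as its last covariate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .stgpr import GPRConfig, GPPosterior, gpr_posterior
from .synthetic import PROPORTION_COVARIATES, GeographyMap

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateModelConfig", "SplineMixedFit",
    "natural_spline_basis", "fit_covariate_stage1", "covariate_gpr",
    "complete_covariates", "province_indicator_series",
]


@dataclass(frozen=True)
class CovariateModelConfig:
    interior_knots: tuple[float, ...] = (2000.0,)
    default_obs_variance: float = 0.05 ** 2   # transformed scale
    gpr: GPRConfig = GPRConfig(amplitude=0.3, length_scale=10.0, nu=1.5,
                               n_draws=2)
    n_draws: int = 0                          # posterior draws kept per series


def _logit(p):
    return np.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------

def natural_spline_basis(years, interior_knots=(2000.0,),
                         boundary_knots: tuple[float, float] | None = None
                         ) -> np.ndarray:
    """Natural cubic spline basis, linear beyond the boundary knots.

    Returns ``1 + len(interior_knots)`` columns (excluding the intercept):
    the linear term plus one curvature term per interior knot, using the
    standard truncated-power construction with the natural (second
    derivative zero at the boundaries) constraint.
    """
    x = np.asarray(years, dtype=float)
    if boundary_knots is None:
        boundary_knots = (float(x.min()), float(x.max()))
    lo, hi = boundary_knots
    if lo >= hi:
        raise ValueError("degenerate boundary knots")
    interior = sorted(float(k) for k in interior_knots)
    if any(not lo < k < hi for k in interior):
        raise ValueError("interior knots must lie strictly inside boundaries")
    knots = np.array([lo, *interior, hi])
    K = len(knots)
    if K == 2:
        return x[:, None].copy()

    def d(k):
        num = (np.maximum(x - knots[k], 0.0) ** 3
               - np.maximum(x - knots[K - 1], 0.0) ** 3)
        return num / (knots[K - 1] - knots[k])

    dK1 = d(K - 2)
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Step 1: mixed-effects spline regression
# ---------------------------------------------------------------------------

@dataclass
class SplineMixedFit:
    fixed_effects: np.ndarray            # intercept + basis coefficients
    random_effects: pd.DataFrame         # group x [intercept, slope]
    resid_var: float
    fitted: pd.DataFrame                 # group, year, mean (transformed scale)
    method: str                          # "reml" | "ml" | "ols"
    basis_knots: tuple
    boundary_knots: tuple[float, float]


def fit_covariate_stage1(obs: pd.DataFrame, groups: list[str],
                         years: list[int],
                         config: CovariateModelConfig = CovariateModelConfig(),
                         group_col: str = "district",
                         value_col: str = "value") -> SplineMixedFit:
    """Mixed-effects natural-spline fit of one covariate series.

    ``obs`` holds one row per observation on the transformed scale
    (columns ``group_col``, ``year``, ``value_col``).  Random effects are a
    per-group intercept and slope on centred year.  Estimation is REML with
    a maximum-likelihood retry, then a fixed-effects-only ordinary least
    squares fallback; groups with no data receive the fixed-effects curve.
    """
    if len(obs) < 2:
        raise ValueError("need at least two observations")
    lo = float(min(min(obs["year"]), min(years)))
    hi = float(max(max(obs["year"]), max(years)))
    interior = tuple(k for k in config.interior_knots if lo < k < hi)
    basis = natural_spline_basis(obs["year"].to_numpy(float), interior, (lo, hi))
    X = np.column_stack([np.ones(len(obs)), basis])
    y = obs[value_col].to_numpy(float)
    g = obs[group_col].to_numpy()
    tc = obs["year"].to_numpy(float) - 2000.0

    method = "ols"
    fe = None
    re = pd.DataFrame(0.0, index=pd.Index(groups, name=group_col),
                      columns=["intercept", "slope"])
    resid_var = float(np.var(y)) or 1.0
    n_groups = len(np.unique(g))
    if n_groups >= 3 and len(obs) > X.shape[1] + 2:
        exog_re = np.column_stack([np.ones(len(obs)), tc])
        for reml in (True, False):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    model = sm.MixedLM(y, X, groups=g, exog_re=exog_re)
                    res = model.fit(reml=reml, method="lbfgs", maxiter=200)
                if not np.isfinite(res.fe_params).all():
                    raise ValueError("non-finite fixed effects")
                fe = np.asarray(res.fe_params)
                for grp, eff in res.random_effects.items():
                    re.loc[grp, "intercept"] = float(eff.iloc[0])
                    re.loc[grp, "slope"] = float(eff.iloc[1]) if len(eff) > 1 else 0.0
                resid_var = float(res.scale)
                method = "reml" if reml else "ml"
                break
            except Exception as err:      # singular fits, convergence failures
                logger.debug("mixed fit (%s) failed: %s",
                             "reml" if reml else "ml", err)
    if fe is None:
        if method == "ols":
            logger.warning("mixed model unavailable; falling back to "
                           "fixed-effects-only least squares")
        fe, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_var = float(np.mean((y - X @ fe) ** 2)) or 1e-6

    yrs = np.array(years, dtype=float)
    Xg = np.column_stack([np.ones(len(yrs)),
                          natural_spline_basis(yrs, interior, (lo, hi))])
    fixed_curve = Xg @ fe
    frames = []
    for grp in groups:
        mean = fixed_curve + re.loc[grp, "intercept"] + \
            re.loc[grp, "slope"] * (yrs - 2000.0)
        frames.append(pd.DataFrame({group_col: grp, "year": years, "mean": mean}))
    fitted = pd.concat(frames, ignore_index=True)
    return SplineMixedFit(fe, re, resid_var, fitted, method, interior, (lo, hi))


# ---------------------------------------------------------------------------
# Step 2: Gaussian process around the spline mean
# ---------------------------------------------------------------------------

def covariate_gpr(fit: SplineMixedFit, obs: pd.DataFrame,
                  config: CovariateModelConfig = CovariateModelConfig(),
                  group_col: str = "district",
                  value_col: str = "value") -> tuple[pd.DataFrame,
                                                     list[GPPosterior]]:
    """GP posterior per group with the spline fit as prior mean.

    Returns the completed series (posterior mean on the transformed scale)
    and the per-group posteriors (for draws).  Observation noise comes from
    the ``variance`` column when present, else the configured default.
    """
    mean = fit.fitted.rename(columns={group_col: "district",
                                      "mean": "mean_logit"})
    o = obs.rename(columns={group_col: "district",
                            value_col: "logit_estimate"}).copy()
    if "variance" in o.columns:
        o["logit_variance"] = o["variance"].astype(float) \
            .fillna(config.default_obs_variance)
    else:
        o["logit_variance"] = config.default_obs_variance
    o["logit_variance"] = np.maximum(o["logit_variance"], 1e-6)
    posteriors = gpr_posterior(mean, o, config.gpr)
    frames = [pd.DataFrame({group_col: p.district,
                            "year": p.years.astype(int),
                            "mean": p.mean,
                            "sd": np.sqrt(np.maximum(np.diag(p.cov), 0.0))})
              for p in posteriors]
    return pd.concat(frames, ignore_index=True), posteriors


# ---------------------------------------------------------------------------
# Whole-covariate orchestration
# ---------------------------------------------------------------------------

def _transform(cov: str, v: np.ndarray) -> np.ndarray:
    if cov in PROPORTION_COVARIATES:
        return _logit(np.clip(v, 1e-4, 1 - 1e-4))
    if cov in ("hhsize", "hfpc"):
        return np.log(np.maximum(v, 1e-6))
    return v  # education: identity


def _back_transform(cov: str, z: np.ndarray) -> np.ndarray:
    if cov in PROPORTION_COVARIATES:
        return _invlogit(z)
    if cov in ("hhsize", "hfpc"):
        return np.exp(z)
    return np.maximum(z, 0.0)


def complete_covariates(cov_obs: pd.DataFrame, districts: list[str],
                        years: list[int],
                        config: CovariateModelConfig = CovariateModelConfig()
                        ) -> pd.DataFrame:
    """Completed wide covariate surface for every district-year.

    Each covariate is modeled independently on its transformed scale.  The
    facilities-per-capita covariate is time-constant (observed in a single
    facility-census year) and bypasses the two-step model: each district
    gets its observed value (source-averaged), with the cross-district mean
    as fallback.
    """
    idx = pd.MultiIndex.from_product([districts, years],
                                     names=["district", "year"])
    out = pd.DataFrame(index=idx).reset_index()
    for cov, g in cov_obs.groupby("covariate", sort=False):
        if cov == "hfpc":
            per_d = g.groupby("district")["value"].mean()
            fallback = float(per_d.mean())
            out[cov] = out["district"].map(per_d).fillna(fallback)
            continue
        obs = g[["district", "year", "value", "variance"]].copy() \
            if "variance" in g.columns else g[["district", "year", "value"]].copy()
        obs["value"] = _transform(cov, obs["value"].to_numpy(float))
        fit = fit_covariate_stage1(obs, districts, years, config)
        done, _ = covariate_gpr(fit, obs, config)
        wide = done.set_index(["district", "year"])["mean"]
        out[cov] = _back_transform(
            cov, wide.reindex(list(zip(out["district"], out["year"]))).to_numpy())
    missing = out.drop(columns=["district", "year"]).isna().any()
    if missing.any():
        raise ValueError(f"incomplete covariate surface: "
                         f"{list(missing[missing].index)}")
    return out


def province_indicator_series(logit_obs: pd.DataFrame, geo: GeographyMap,
                              years: list[int],
                              config: CovariateModelConfig = CovariateModelConfig()
                              ) -> pd.DataFrame:
    """Province-year indicator series via the same two-step model.

    District logit observations are aggregated to province-year-source cells
    by precision weighting (rows with a province label but no district —
    surveys lacking district identifiers — contribute directly), then the
    spline mixed model and GP run across provinces.  Values return on the
    coverage scale.
    """
    obs = logit_obs.copy()
    if "province" not in obs.columns or obs["province"].isna().any():
        obs["province"] = obs["province"] if "province" in obs.columns else np.nan
        mask = obs["province"].isna() & obs["district"].notna()
        obs.loc[mask, "province"] = obs.loc[mask, "district"].map(geo.province_of)
    rows = []
    for (ind, prov, year, src), g in obs.groupby(
            ["indicator", "province", "year", "source"], sort=False):
        w = 1.0 / np.maximum(g["logit_variance"].to_numpy(float), 1e-8)
        est = float((w * g["logit_estimate"].to_numpy(float)).sum() / w.sum())
        rows.append((ind, prov, int(year), src, est, 1.0 / w.sum()))
    agg = pd.DataFrame(rows, columns=["indicator", "province", "year",
                                      "source", "value", "variance"])
    frames = []
    provinces = list(geo.provinces)
    for ind, g in agg.groupby("indicator", sort=False):
        empty = set(provinces) - set(g["province"])
        if empty:
            logger.warning("%s: provinces %s have no observations; using the "
                           "fixed-effects curve", ind, sorted(empty))
        fit = fit_covariate_stage1(g, provinces, years, config,
                                   group_col="province")
        done, _ = covariate_gpr(fit, g, config, group_col="province")
        done = done.rename(columns={"province": "province"})
        done.insert(0, "indicator", ind)
        done["value"] = _invlogit(done["mean"].to_numpy(float))
        done["flag_no_data"] = done["province"].isin(empty)
        frames.append(done[["indicator", "province", "year", "value",
                            "sd", "flag_no_data"]])
    return pd.concat(frames, ignore_index=True)
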