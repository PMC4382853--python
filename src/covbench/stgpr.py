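"""Three-stage small-area estimator for sparse bounded indicators.

Stage 1 is an ordinary least squares regression of the logit-transformed
indicator on district-year covariates (electricity, female headship,
household size, women's education, improved walls, facilities per capita)
plus the province-level series of the same indicator:

    logit(Ind)_{i,k,t} = b0 + b1 t + b2 elec + b3 fhead + b4 hhsize
                         + b5 edu + b6 wall + b7 HFPC + b8 Ind_{k,t} + e

Stage 2 smooths the stage-1 residuals with locally weighted averaging over
space (districts in the same province) and time (tricube kernel), and adds
the smoothed residual back onto the linear prediction.

Stage 3 runs an independent Gaussian process per district over years, with
the stage-2 surface as prior mean, a Matérn covariance in time, and the
logit-space sampling variances as heteroskedastic observation noise.
Posterior draws (default 1,000) are inverse-logit transformed into the draw
cube from which means and 95% uncertainty intervals are summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import linalg

from .synthetic import COVARIATE_ORDER, GeographyMap

logger = logging.getLogger(__name__)

__all__ = [
    "STConfig", "GPRConfig", "Stage1Fit", "GPPosterior", "STGPRResult",
    "fit_stage1", "st_weights", "smooth_residuals", "matern_cov",
    "gpr_posterior", "draw_estimates", "summarize", "run_stgpr",
]

DESIGN_COLUMNS = ["intercept", "t"] + COVARIATE_ORDER + ["ind"]


@dataclass(frozen=True)
class STConfig:
    """Spatial-temporal residual smoothing parameters."""

    lambda_years: float = 10.0      # temporal bandwidth of the tricube kernel
    zeta: float = 0.5               # weight of same-province (other-district) residuals
    kernel: str = "tricube"

    def __post_init__(self):
        if self.lambda_years <= 0:
            raise ValueError("temporal bandwidth must be positive")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        if self.kernel != "tricube":
            raise ValueError("only the tricube kernel is implemented")


@dataclass(frozen=True)
class GPRConfig:
    """Gaussian-process stage parameters (logit scale).

    ``amplitude=None`` estimates the Matérn amplitude per indicator as the
    standard deviation of the data residuals around the stage-2 mean
    (floored at ``amplitude_floor``).
    """

    amplitude: float | None = None
    amplitude_floor: float = 0.1
    length_scale: float = 5.0       # years; program scale-ups move coverage
                                    # on roughly this time scale
    nu: float = 1.5
    n_draws: int = 1000
    seed: int = 0
    jitter: float = 1e-8
    max_jitter: float = 1e-2

    def __post_init__(self):
        if self.amplitude is not None and self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.length_scale <= 0:
            raise ValueError("length scale must be positive")
        if self.nu not in (0.5, 1.5, 2.5):
            raise ValueError("nu must be one of 0.5, 1.5, 2.5")
        if self.n_draws < 2:
            raise ValueError("need at least two draws")


@dataclass
class Stage1Fit:
    """OLS fit of one indicator in logit space."""

    indicator: str
    beta: pd.Series                      # indexed by DESIGN_COLUMNS
    fitted: pd.DataFrame                 # district, year, pred_logit
    residuals: pd.DataFrame              # obs rows + resid column
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class GPPosterior:
    district: str
    years: np.ndarray
    mean: np.ndarray
    cov: np.ndarray


@dataclass
class STGPRResult:
    cube: xr.DataArray                   # (indicator, district, year, draw)
    summary: pd.DataFrame                # indicator, district, year, mean, lower, upper
    stage1: dict[str, Stage1Fit]
    stage2_mean: pd.DataFrame            # indicator, district, year, mean_logit
    diagnostics: pd.DataFrame


# ---------------------------------------------------------------------------
# Stage 1: OLS in logit space
# ---------------------------------------------------------------------------

def _design_frame(df: pd.DataFrame, prov_ind: pd.DataFrame, indicator: str,
                  geo: GeographyMap) -> pd.DataFrame:
    """Attach the province indicator series as the ``ind`` column."""
    sub = prov_ind[prov_ind["indicator"] == indicator]
    out = df.copy()
    if "province" not in out.columns or out["province"].isna().any():
        out["province"] = out["district"].map(geo.province_of)
    out = out.merge(sub[["province", "year", "value"]].rename(columns={"value": "ind"}),
                    on=["province", "year"], how="left")
    return out


def _design_matrix(df: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([
        np.ones(len(df)),
        df["year"].to_numpy(float) - 2000.0,
        *[df[c].to_numpy(float) for c in COVARIATE_ORDER],
        df["ind"].to_numpy(float),
    ])
    return X


def fit_stage1(obs: pd.DataFrame, covariates: pd.DataFrame,
               province_ind: pd.DataFrame, geo: GeographyMap,
               indicator: str | None = None,
               weighted: bool = False) -> Stage1Fit:
    """Unweighted OLS of one indicator's logit observations on covariates.

    ``obs`` needs columns district, year, logit_estimate (and logit_variance
    if ``weighted``); ``covariates`` is the completed wide surface with one
    row per district-year.  Returns coefficients, fitted logit values for
    every district-year in the covariate frame, and residuals at observed
    cells.  Collinear columns are dropped with a warning and reported.
    """
    if indicator is None:
        inds = obs["indicator"].unique()
        if len(inds) != 1:
            raise ValueError("pass a single indicator or filter obs first")
        indicator = str(inds[0])
    else:
        obs = obs[obs["indicator"] == indicator]
    obs = obs.dropna(subset=["district"])
    if len(obs) < 10:
        raise ValueError(f"{indicator}: need at least 10 observations")

    merged = obs.merge(covariates, on=["district", "year"], how="left",
                       suffixes=("", "_cov"))
    merged = _design_frame(merged, province_ind, indicator, geo)
    missing = merged[COVARIATE_ORDER + ["ind"]].isna().any(axis=1)
    if missing.any():
        raise ValueError(f"{indicator}: {int(missing.sum())} observations lack "
                         "covariate values")
    y = merged["logit_estimate"].to_numpy(float)
    X = _design_matrix(merged)
    w = None
    if weighted:
        w = 1.0 / np.maximum(merged["logit_variance"].to_numpy(float), 1e-8)
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y

    keep = list(range(X.shape[1]))
    dropped: list[str] = []
    rank = np.linalg.matrix_rank(Xw)
    if rank < Xw.shape[1]:
        # Pivoted QR: keep the first `rank` pivot columns, intercept always kept.
        _, _, piv = linalg.qr(Xw, mode="economic", pivoting=True)
        keep = sorted(set(piv[:rank]) | {0})
        dropped = [DESIGN_COLUMNS[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("%s: design rank-deficient, dropping %s", indicator, dropped)
    beta_full = np.zeros(X.shape[1])
    sol, *_ = np.linalg.lstsq(Xw[:, keep], yw, rcond=None)
    beta_full[keep] = sol

    pred_frame = _design_frame(covariates, province_ind, indicator, geo)
    fitted = pred_frame[["district", "year"]].copy()
    fitted["pred_logit"] = _design_matrix(pred_frame) @ beta_full

    resid = merged[["district", "province", "year", "source",
                    "logit_estimate", "logit_variance"]].copy()
    resid["resid"] = y - X @ beta_full
    beta = pd.Series(beta_full, index=DESIGN_COLUMNS, name=indicator)
    return Stage1Fit(indicator, beta, fitted, resid, dropped)


# ---------------------------------------------------------------------------
# Stage 2: spatial-temporal residual smoothing
# ---------------------------------------------------------------------------

def _tricube(dt: np.ndarray, lam: float) -> np.ndarray:
    u = np.abs(dt) / (lam + 1.0)
    w = (1.0 - u ** 3) ** 3
    return np.where(np.abs(dt) <= lam, np.maximum(w, 0.0), 0.0)


def st_weights(target: tuple[str, int], datum: tuple[str, int],
               geo: GeographyMap, config: STConfig = STConfig()) -> float:
    """Weight of one observed residual for one target district-year.

    The weight factorizes into a spatial factor (1 in the same district,
    ``zeta`` for another district in the same province, 0 across provinces)
    and a tricube temporal factor with bandwidth ``lambda_years``.
    """
    (td, ty), (dd, dy) = target, datum
    pmap = geo.province_of
    if td == dd:
        sp = 1.0
    elif pmap[td] == pmap[dd]:
        sp = config.zeta
    else:
        return 0.0
    return float(sp * _tricube(np.array([ty - dy], float), config.lambda_years)[0])


def smooth_residuals(fit: Stage1Fit, geo: GeographyMap, years: list[int],
                     config: STConfig = STConfig()) -> pd.DataFrame:
    """Stage-2 mean surface: stage-1 prediction plus smoothed residuals.

    The smoothed residual at a cell is the weighted mean of observed
    residuals under the spatial-temporal weights; cells with zero total
    weight fall back to the stage-1 prediction alone.
    """
    res = fit.residuals
    obs_d = res["district"].to_numpy()
    obs_p = res["province"].to_numpy()
    obs_t = res["year"].to_numpy(float)
    obs_r = res["resid"].to_numpy(float)
    yarr = np.array(years, dtype=float)
    tw = _tricube(yarr[:, None] - obs_t[None, :], config.lambda_years)

    pmap = geo.province_of
    rows = []
    for d in geo.district_ids:
        sp = np.where(obs_d == d, 1.0,
                      np.where(obs_p == pmap[d], config.zeta, 0.0))
        W = tw * sp[None, :]
        tot = W.sum(axis=1)
        sm = np.divide(W @ obs_r, tot, out=np.zeros_like(tot), where=tot > 0)
        rows.append(pd.DataFrame({"district": d, "year": years, "smoothed": sm}))
    smoothed = pd.concat(rows, ignore_index=True)
    out = fit.fitted.merge(smoothed, on=["district", "year"], how="left")
    out["mean_logit"] = out["pred_logit"] + out["smoothed"].fillna(0.0)
    return out[["district", "year", "pred_logit", "smoothed", "mean_logit"]]


# ---------------------------------------------------------------------------
# Stage 3: Gaussian process regression
# ---------------------------------------------------------------------------

def matern_cov(delta_t, config: GPRConfig) -> np.ndarray:
    """Matérn covariance of a time lag, for nu in {1/2, 3/2, 5/2}."""
    d = np.abs(np.asarray(delta_t, dtype=float))
    sigma = config.amplitude
    if sigma is None:
        raise ValueError("amplitude not set; estimate it or fix it in config")
    r = d / config.length_scale
    if config.nu == 0.5:
        k = np.exp(-r)
    elif config.nu == 1.5:
        s = np.sqrt(3.0) * r
        k = (1.0 + s) * np.exp(-s)
    elif config.nu == 2.5:
        s = np.sqrt(5.0) * r
        k = (1.0 + s + s * s / 3.0) * np.exp(-s)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError("nu must be one of 0.5, 1.5, 2.5")
    return sigma ** 2 * k


def _chol_with_jitter(K: np.ndarray, config: GPRConfig, label: str):
    jit = config.jitter
    while True:
        try:
            return linalg.cholesky(K + jit * np.eye(len(K)), lower=True)
        except linalg.LinAlgError:
            jit *= 10.0
            if jit > config.max_jitter:
                raise linalg.LinAlgError(
                    f"Cholesky failed for {label} even with jitter {jit:.0e}")


def gpr_posterior(mean: pd.DataFrame, obs: pd.DataFrame, config: GPRConfig,
                  district: str | None = None) -> GPPosterior | list[GPPosterior]:
    """Per-district GP posterior over years (logit scale).

    ``mean`` holds the prior mean (columns district, year, mean_logit);
    ``obs`` the observations (district, year, logit_estimate,
    logit_variance).  Districts are independent GPs; with no observations
    the posterior equals the prior.  Multiple sources in the same
    district-year enter as separate noisy observations.
    """
    if district is None:
        return [gpr_posterior(mean, obs, config, d)
                for d in mean["district"].unique()]
    sub = mean[mean["district"] == district].sort_values("year")
    years = sub["year"].to_numpy(float)
    m = sub["mean_logit"].to_numpy(float)
    K = matern_cov(years[:, None] - years[None, :], config)
    o = obs[obs["district"] == district]
    if o.empty:
        return GPPosterior(district, years, m, K)
    oy = o["year"].to_numpy(float)
    yv = o["logit_estimate"].to_numpy(float)
    noise = o["logit_variance"].to_numpy(float)
    # prior mean at observation years (years grid is annual and complete)
    pos = np.searchsorted(years, oy)
    if not np.all(years[pos] == oy):
        raise ValueError(f"{district}: observation year outside the frame")
    m_obs = m[pos]
    K_oo = matern_cov(oy[:, None] - oy[None, :], config) + np.diag(noise)
    K_star = matern_cov(years[:, None] - oy[None, :], config)
    L = _chol_with_jitter(K_oo, config, f"district {district}")
    alpha = linalg.cho_solve((L, True), yv - m_obs)
    V = linalg.solve_triangular(L, K_star.T, lower=True)
    post_mean = m + K_star @ alpha
    post_cov = K - V.T @ V
    return GPPosterior(district, years, post_mean, post_cov)


def draw_estimates(posteriors: list[GPPosterior], config: GPRConfig,
                   indicator: str = "indicator",
                   stream: tuple[int, ...] = ()) -> xr.DataArray:
    """Seeded multivariate-normal draws, inverse-logit transformed.

    Returns a (district, year, draw) array in coverage space, strictly
    inside (0, 1).  The random stream is keyed on (seed, *stream,
    district index) so cubes are reproducible and independent across
    indicators.
    """
    districts = [p.district for p in posteriors]
    years = posteriors[0].years
    out = np.empty((len(districts), len(years), config.n_draws))
    for i, post in enumerate(posteriors):
        rng = np.random.default_rng([config.seed, *stream, i])
        L = _chol_with_jitter(post.cov, config, f"draws for {post.district}")
        z = rng.standard_normal((len(years), config.n_draws))
        logits = post.mean[:, None] + L @ z
        out[i] = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
    return xr.DataArray(
        out, name="coverage",
        coords={"district": districts, "year": [int(y) for y in years],
                "draw": np.arange(config.n_draws)},
        dims=("district", "year", "draw"))


def summarize(cube: xr.DataArray) -> pd.DataFrame:
    """Mean and 2.5/97.5 percentile of draws per cell (coverage space)."""
    if cube.sizes["draw"] < 2:
        raise ValueError("need at least two draws")
    axis = cube.dims.index("draw")
    vals = cube.values
    mean_v = vals.mean(axis=axis)
    lo_v, hi_v = np.quantile(vals, [0.025, 0.975], axis=axis, method="linear")
    rest = [d for d in cube.dims if d != "draw"]
    coords = {d: cube.coords[d] for d in rest}
    df = xr.Dataset({"mean": xr.DataArray(mean_v, coords=coords, dims=rest),
                     "lower": xr.DataArray(lo_v, coords=coords, dims=rest),
                     "upper": xr.DataArray(hi_v, coords=coords, dims=rest)}) \
        .to_dataframe().reset_index()
    front = [c for c in ("indicator", "district", "year") if c in df.columns]
    return df[front + ["mean", "lower", "upper"]]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_stgpr(obs: pd.DataFrame, covariates: pd.DataFrame,
              province_ind: pd.DataFrame, geo: GeographyMap,
              years: list[int],
              st_config: STConfig = STConfig(),
              gpr_config: GPRConfig = GPRConfig(),
              indicators: list[str] | None = None) -> STGPRResult:
    """Run the three stages for each indicator and assemble the draw cube."""
    if indicators is None:
        indicators = sorted(obs["indicator"].unique())
    cubes, stage1, stage2_frames, diag = {}, {}, [], []
    for j, ind in enumerate(indicators):
        fit = fit_stage1(obs, covariates, province_ind, geo, ind)
        mean2 = smooth_residuals(fit, geo, years, st_config)
        sub = obs[(obs["indicator"] == ind) & obs["district"].notna()]
        merged = sub.merge(mean2[["district", "year", "mean_logit"]],
                           on=["district", "year"], how="left")
        resid2 = merged["logit_estimate"] - merged["mean_logit"]
        cfg = gpr_config
        if cfg.amplitude is None:
            amp = float(max(np.std(resid2.to_numpy(float)), cfg.amplitude_floor))
            cfg = replace(cfg, amplitude=amp)
        posteriors = gpr_posterior(mean2, sub, cfg)
        cube = draw_estimates(posteriors, cfg, ind, stream=(j,))
        cubes[ind] = cube
        stage1[ind] = fit
        m2 = mean2.copy()
        m2.insert(0, "indicator", ind)
        stage2_frames.append(m2)
        diag.append((ind, cfg.amplitude, float(np.std(fit.residuals["resid"])),
                     len(sub), fit.beta["t"]))
        logger.info("%s: stage-1 resid SD %.3f, GP amplitude %.3f, %d obs",
                    ind, diag[-1][2], cfg.amplitude, len(sub))
    cube = xr.concat([cubes[i] for i in indicators],
                     dim=pd.Index(indicators, name="indicator"))
    cube.attrs.update(seed=gpr_config.seed, n_draws=gpr_config.n_draws,
                      nu=gpr_config.nu, length_scale=gpr_config.length_scale,
                      lambda_years=st_config.lambda_years, zeta=st_config.zeta)
    summary = summarize(cube)
    diagnostics = pd.DataFrame(
        diag, columns=["indicator", "gp_amplitude", "stage1_resid_sd",
                       "n_obs", "trend_coef"])
    return STGPRResult(cube, summary, stage1,
                       pd.concat(stage2_frames, ignore_index=True), diagnostics)
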