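"""Synthetic study generator: geographies, true coverage surfaces, covariates,
populations, administrative spray counts, and sparse noisy survey observations.

The generator emulates the data situation of a district-level coverage
benchmarking exercise in a country whose administrative geography was refined
mid-period (old coarse districts splitting into several new ones), where
coverage of each intervention is observed only through a handful of household
surveys with design-inflated binomial sampling error, plus administrative
counts for indoor residual spraying.

Ground truth is generated *from* the downstream model's own functional form —
a logit-linear predictor on district-year covariates plus smooth province- and
district-level temporal shocks — so that parameter-recovery and calibration
tests are well posed.  All generators are pure functions of their inputs and a
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import digamma, polygamma

logger = logging.getLogger(__name__)

__all__ = [
    "GeographyMap",
    "IndicatorSpec",
    "Scenario",
    "SurveySource",
    "SyntheticTruth",
    "PopulationTable",
    "default_scenario",
    "default_survey_plan",
    "generate_geography",
    "generate_truth",
    "generate_population",
    "generate_admin_irs",
    "sample_observations",
    "sample_covariate_observations",
    "recode_to_old_geography",
]

# Columns of the long-format observation table shared across the package.
OBS_COLUMNS = [
    "indicator", "district", "province", "year", "source",
    "estimate", "variance", "sample_size", "flag_floor", "flag_split_adjusted",
]

# Stage-1 covariates in the order the coefficient vector is reported.
COVARIATE_ORDER = ["elec", "fhead", "hhsize", "edu", "wall", "hfpc"]
# Extra socio-demographic surfaces generated only for the SES composite.
SES_EXTRA_COVARIATES = ["sanitation", "fuel"]
PROPORTION_COVARIATES = {"elec", "fhead", "wall", "sanitation", "fuel"}


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _invlogit(x):
    x = np.clip(np.asarray(x, dtype=float), -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeographyMap:
    """Districts, their provinces, and the old->new split lineage.

    ``lineage`` maps every *old* district id to the tuple of new districts it
    became; unsplit districts map to a single inheritor.  ``shares`` gives
    each new district's population share within its old parent (1.0 for
    unsplit districts).
    """

    provinces: tuple[str, ...]
    districts: tuple[tuple[str, str], ...]          # (district, province)
    lineage: dict[str, tuple[str, ...]]              # old id -> new ids
    shares: dict[str, float]                         # new id -> share in parent

    @property
    def district_ids(self) -> list[str]:
        return [d for d, _ in self.districts]

    @property
    def province_of(self) -> dict[str, str]:
        return dict(self.districts)

    @property
    def split_map(self) -> dict[str, tuple[str, ...]]:
        """Only the old districts that split into two or more inheritors."""
        return {o: kids for o, kids in self.lineage.items() if len(kids) > 1}

    @property
    def parent_of(self) -> dict[str, str]:
        return {d: o for o, kids in self.lineage.items() for d in kids}

    def validate(self) -> None:
        pmap = self.province_of
        if set(pmap.values()) - set(self.provinces):
            raise ValueError("district assigned to unknown province")
        seen: set[str] = set()
        for old, kids in self.lineage.items():
            if seen & set(kids):
                raise ValueError(f"inheritors of {old} overlap another parent")
            seen.update(kids)
            s = sum(self.shares[d] for d in kids)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"shares of {old} sum to {s}, not 1")
        if seen != set(self.district_ids):
            raise ValueError("lineage does not cover all districts")


def generate_geography(n_provinces: int, n_districts: int,
                       n_split_parents: int, seed: int) -> GeographyMap:
    """Build a random administrative geography with split lineage.

    ``n_split_parents`` old districts each split into two new districts
    (within one province); the remaining old districts carry over one-to-one,
    so the old geography has ``n_districts - n_split_parents`` + pairs.
    """
    if n_provinces < 1 or n_districts < 1:
        raise ValueError("counts must be positive")
    if n_split_parents < 0:
        raise ValueError("counts must be positive")
    if n_districts < n_provinces:
        raise ValueError("need at least one district per province")
    if n_split_parents > n_districts // 2:
        raise ValueError("at most n_districts/2 split parents")

    rng = np.random.default_rng(seed)
    provinces = tuple(f"P{i+1}" for i in range(n_provinces))
    # Distribute districts as evenly as possible, remainder at random.
    sizes = np.full(n_provinces, n_districts // n_provinces)
    extra = rng.choice(n_provinces, n_districts % n_provinces, replace=False)
    sizes[extra] += 1

    width = len(str(n_districts))
    districts: list[tuple[str, str]] = []
    i = 0
    for prov, size in zip(provinces, sizes):
        for _ in range(size):
            districts.append((f"D{i+1:0{width}d}", prov))
            i += 1

    # Candidate split pairs: disjoint pairs of districts within a province.
    pairs: list[tuple[str, str]] = []
    for prov in provinces:
        ids = [d for d, p in districts if p == prov]
        ids = [ids[j] for j in rng.permutation(len(ids))]
        pairs.extend(zip(ids[0::2], ids[1::2]))
    if n_split_parents > len(pairs):
        raise ValueError("not enough within-province pairs to split")
    chosen = [pairs[j] for j in
              rng.choice(len(pairs), n_split_parents, replace=False)] if pairs else []

    lineage: dict[str, tuple[str, ...]] = {}
    shares: dict[str, float] = {}
    in_pair = {d for pair in chosen for d in pair}
    k = 0
    owidth = max(width, 2)
    for pair in chosen:
        old = f"O{k+1:0{owidth}d}"
        k += 1
        lineage[old] = tuple(pair)
        s = rng.uniform(0.3, 0.7)
        shares[pair[0]], shares[pair[1]] = s, 1.0 - s
    for d, _ in districts:
        if d not in in_pair:
            old = f"O{k+1:0{owidth}d}"
            k += 1
            lineage[old] = (d,)
            shares[d] = 1.0
    geo = GeographyMap(provinces, tuple(districts), lineage, shares)
    geo.validate()
    return geo


# ---------------------------------------------------------------------------
# Scenario: indicator roster and generating parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorSpec:
    """Generating parameters for one indicator's true coverage surface.

    ``kind`` is ``"vertical"`` (program launched mid-period; coverage is
    clamped to 1e-4 before ``launch_year`` and scales up through the
    province-level program-intensity ramp) or ``"routine"`` (service present
    throughout, linear logit trend).  ``floor_year`` is the preprocessing
    assumption year: all cells strictly before it are floored at 0.01%
    coverage downstream.
    """

    name: str
    kind: str                      # "vertical" | "routine"
    beta0: float                   # intercept, logit units
    trend: float                   # common logit trend per year (beta1)
    ind_effect: float              # loading on the province indicator series (beta8)
    launch_year: int | None = None
    floor_year: int | None = None
    ramp_mid: float = 2004.0       # centre of the vertical scale-up ramp
    ramp_scale: float = 1.8        # years; ramp steepness
    routine_level: float = 0.7     # typical province-series level for routine
    slope_sd: float = 0.0          # SD of district-specific logit trend deviations
    convergence: float = 0.0       # >0: high-baseline districts trend down


@dataclass(frozen=True)
class Scenario:
    """Full generating configuration for one synthetic study."""

    indicators: tuple[IndicatorSpec, ...]
    years: tuple[int, int] = (1990, 2010)
    covariate_betas: dict = field(default_factory=lambda: {
        "elec": 0.8, "fhead": -0.3, "hhsize": -0.05,
        "edu": 0.15, "wall": 0.5, "hfpc": 0.3,
    })
    province_shock_sd: float = 0.15
    district_shock_sd: float = 0.20
    district_intercept_sd: float = 0.30
    ar_coef: float = 0.85
    mean_household_size: float = 5.0

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def spec(self, name: str) -> IndicatorSpec:
        for s in self.indicators:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def launch_years(self) -> dict[str, int]:
        return {s.name: s.launch_year for s in self.indicators
                if s.launch_year is not None}

    @property
    def floor_years(self) -> dict[str, int]:
        return {s.name: s.floor_year for s in self.indicators
                if s.floor_year is not None}


def default_scenario() -> Scenario:
    """Default 12-indicator scenario, 1990-2010.

    Four malaria-control verticals (launched around 1999-2003, floored at
    0.01% before 1997), four immunizations (pentavalent launched 2005,
    floored before 2004; polio stagnant with wide district dispersion), and
    four routine maternal/child services (antenatal care and skilled birth
    attendance declining with convergence, exclusive breastfeeding scaling
    up).  Trend magnitudes echo the qualitative patterns of national
    scale-up of verticals and stagnation of routine services.
    """
    # Vertical intercepts sit near logit(1e-4) minus the typical covariate
    # contribution, so true coverage rises continuously out of the pre-launch
    # floor as the province program-intensity ramp takes off.
    mal = dict(kind="vertical", floor_year=1997, ind_effect=13.0, trend=0.02,
               slope_sd=0.03)
    return Scenario(indicators=(
        IndicatorSpec("itn", beta0=-10.2, launch_year=1999, ramp_mid=2004, **mal),
        IndicatorSpec("irs", beta0=-10.8, launch_year=1999, ramp_mid=2006, **mal),
        IndicatorSpec("itn_or_irs", beta0=-9.9, launch_year=1999, ramp_mid=2004, **mal),
        IndicatorSpec("iptp2", beta0=-10.4, launch_year=2003, ramp_mid=2006, **mal),
        IndicatorSpec("bcg", "routine", beta0=1.0, trend=0.015, ind_effect=0.5,
                      routine_level=0.88, slope_sd=0.02),
        IndicatorSpec("measles", "routine", beta0=0.6, trend=0.01, ind_effect=0.5,
                      routine_level=0.82, slope_sd=0.02),
        IndicatorSpec("polio", "routine", beta0=0.7, trend=0.0, ind_effect=0.5,
                      routine_level=0.81, slope_sd=0.06, convergence=0.12),
        IndicatorSpec("penta", "vertical", beta0=-10.1, trend=0.02, ind_effect=14.0,
                      launch_year=2005, floor_year=2004, ramp_mid=2007,
                      ramp_scale=1.2, slope_sd=0.04),
        IndicatorSpec("anc4", "routine", beta0=0.8, trend=-0.07, ind_effect=0.5,
                      routine_level=0.60, slope_sd=0.04, convergence=0.12),
        IndicatorSpec("sba", "routine", beta0=-0.6, trend=-0.02, ind_effect=0.5,
                      routine_level=0.45, slope_sd=0.06, convergence=0.08),
        IndicatorSpec("ebf", "routine", beta0=-1.8, trend=0.18, ind_effect=0.5,
                      routine_level=0.40, slope_sd=0.03),
        IndicatorSpec("not_underweight", "routine", beta0=1.3, trend=0.02,
                      ind_effect=0.5, routine_level=0.85, slope_sd=0.015),
    ))


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """True surfaces plus everything needed for recovery tests."""

    scenario: Scenario
    geo: GeographyMap
    p: xr.DataArray                      # (indicator, district, year) in (0,1)
    covariates: pd.DataFrame             # district, year, <covariate columns>
    province_ind: pd.DataFrame           # indicator, province, year, value
    betas: pd.DataFrame                  # indicator x coefficient (9 columns)
    seed: int

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.p.coords["year"].values]

    @property
    def indicators(self) -> list[str]:
        return [str(i) for i in self.p.coords["indicator"].values]

    def validate(self) -> None:
        v = self.p.values
        if not ((v > 0) & (v < 1)).all():
            raise ValueError("true coverage must lie strictly inside (0,1)")
        for s in self.scenario.indicators:
            if s.launch_year is None:
                continue
            pre = self.p.sel(indicator=s.name,
                             year=[y for y in self.years if y < s.launch_year])
            if pre.size and not (pre.values <= 1e-3).all():
                raise ValueError(f"{s.name}: pre-launch coverage above 0.1%")


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) path with marginal SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, innov_sd)
    return x


def _covariate_truth(rng: np.random.Generator, geo: GeographyMap,
                     years: list[int]) -> pd.DataFrame:
    """Smooth per-district covariate surfaces on their natural scales."""
    tc = np.array(years, dtype=float) - 2000.0
    rows = {}
    n = len(geo.district_ids)
    params = {
        # (transform, base level on transformed scale, district sd, mean slope, slope sd)
        "elec": ("logit", _logit(0.18), 0.8, 0.055, 0.02),
        "fhead": ("logit", _logit(0.24), 0.3, 0.004, 0.004),
        "wall": ("logit", _logit(0.35), 0.6, 0.03, 0.012),
        "sanitation": ("logit", _logit(0.30), 0.6, 0.035, 0.012),
        "fuel": ("logit", _logit(0.15), 0.7, 0.04, 0.015),
        "hhsize": ("log", np.log(5.2), 0.08, -0.002, 0.002),
        "edu": ("identity", 4.5, 0.9, 0.05, 0.02),
    }
    for cov, (transform, base, dsd, slope, ssd) in params.items():
        a = rng.normal(base, dsd, n)
        b = rng.normal(slope, ssd, n)
        surf = a[:, None] + b[:, None] * tc[None, :]
        if transform == "logit":
            rows[cov] = _invlogit(surf)
        elif transform == "log":
            rows[cov] = np.exp(surf)
        else:
            rows[cov] = np.maximum(surf, 0.0)
    hfpc = rng.lognormal(np.log(0.5), 0.4, n)   # facilities per 1,000, constant
    idx = pd.MultiIndex.from_product([geo.district_ids, years],
                                     names=["district", "year"])
    out = pd.DataFrame(index=idx).reset_index()
    for cov in params:
        out[cov] = rows[cov].reshape(-1)
    out["hfpc"] = np.repeat(hfpc, len(years))
    return out


def _province_series(rng: np.random.Generator, spec: IndicatorSpec,
                     provinces: tuple[str, ...], years: list[int]) -> np.ndarray:
    """Province-level indicator series used as the beta8 covariate."""
    t = np.array(years, dtype=float)
    out = np.empty((len(provinces), len(t)))
    for k in range(len(provinces)):
        if spec.kind == "vertical":
            mid = spec.ramp_mid + rng.normal(0.0, 1.0)
            hi = rng.uniform(0.6, 0.85)
            ramp = 1.0 / (1.0 + np.exp(-(t - mid) / spec.ramp_scale))
            s = 1e-4 + (hi - 1e-4) * ramp
            if spec.launch_year is not None:
                s = np.where(t < spec.launch_year, 1e-4, s)
        else:
            b0 = _logit(spec.routine_level) + rng.normal(0.0, 0.25)
            b1 = spec.trend * rng.uniform(0.5, 1.5)
            s = _invlogit(b0 + b1 * (t - 2000.0))
        out[k] = s
    return out


def generate_truth(geo: GeographyMap, years: tuple[int, int],
                   scenario: Scenario, seed: int) -> SyntheticTruth:
    """Generate true coverage surfaces from the stage-1 functional form.

    For every indicator, logit(p) = beta0 + beta1*(t-2000) + covariate terms
    + beta8 * province-series + province AR(1) shock + district shock (random
    intercept + trend deviation + AR(1)).  Vertical indicators are clamped to
    exactly 1e-4 coverage before their launch year.
    """
    y0, y1 = years
    if y1 < y0:
        raise ValueError("empty year range")
    for s in scenario.indicators:
        if s.launch_year is not None and not (y0 <= s.launch_year <= y1 + 1):
            raise ValueError(f"{s.name}: launch year outside the year range")
    year_list = list(range(y0, y1 + 1))
    tc = np.array(year_list, dtype=float) - 2000.0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    cov = _covariate_truth(rng, geo, year_list)
    districts = geo.district_ids
    provinces = geo.provinces
    prov_idx = {p: k for k, p in enumerate(provinces)}
    d_prov = np.array([prov_idx[geo.province_of[d]] for d in districts])
    n_d, n_t = len(districts), len(year_list)

    cov_mats = {c: cov[c].to_numpy().reshape(n_d, n_t)
                for c in COVARIATE_ORDER}
    cb = scenario.covariate_betas
    cov_term = sum(cb[c] * cov_mats[c] for c in COVARIATE_ORDER)

    p_cube = np.empty((len(scenario.indicators), n_d, n_t))
    prov_rows = []
    beta_rows = {}
    for j, spec in enumerate(scenario.indicators):
        prov_s = _province_series(rng, spec, provinces, year_list)
        for k, pv in enumerate(provinces):
            for ti, yy in enumerate(year_list):
                prov_rows.append((spec.name, pv, yy, prov_s[k, ti]))
        u = np.stack([_ar1(rng, n_t, scenario.province_shock_sd, scenario.ar_coef)
                      for _ in provinces])
        a_dev = rng.normal(0.0, scenario.district_intercept_sd, n_d)
        slope_dev = -spec.convergence * a_dev + rng.normal(0.0, spec.slope_sd, n_d)
        v = np.stack([a_dev[i] + slope_dev[i] * tc
                      + _ar1(rng, n_t, scenario.district_shock_sd, scenario.ar_coef)
                      for i in range(n_d)])
        eta = (spec.beta0 + spec.trend * tc[None, :] + cov_term
               + spec.ind_effect * prov_s[d_prov] + u[d_prov] + v)
        if spec.launch_year is not None:
            pre = np.array(year_list) < spec.launch_year
            eta[:, pre] = _logit(1e-4)
        p_cube[j] = _invlogit(eta)
        beta_rows[spec.name] = [spec.beta0, spec.trend, cb["elec"], cb["fhead"],
                                cb["hhsize"], cb["edu"], cb["wall"], cb["hfpc"],
                                spec.ind_effect]

    p = xr.DataArray(
        p_cube, name="coverage",
        coords={"indicator": [s.name for s in scenario.indicators],
                "district": districts, "year": year_list},
        dims=("indicator", "district", "year"))
    betas = pd.DataFrame.from_dict(
        beta_rows, orient="index",
        columns=["beta0", "trend"] + COVARIATE_ORDER + ["ind"])
    betas.index.name = "indicator"
    province_ind = pd.DataFrame(prov_rows,
                                columns=["indicator", "province", "year", "value"])
    truth = SyntheticTruth(scenario, geo, p, cov, province_ind, betas, seed)
    truth.validate()
    return truth


def zero_noise_scenario(scenario: Scenario) -> Scenario:
    """Copy of a scenario with all shock processes switched off.

    The resulting truth is exactly the inverse-logit of the stage-1 linear
    predictor, so regression on noiseless data recovers the generating
    coefficients to machine precision.
    """
    return replace(scenario,
                   province_shock_sd=0.0, district_shock_sd=0.0,
                   district_intercept_sd=0.0,
                   indicators=tuple(replace(s, slope_sd=0.0, convergence=0.0)
                                    for s in scenario.indicators))


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationTable:
    """District population and household counts at census anchor years."""

    counts: pd.DataFrame            # district, year, population, households
    census_years: tuple[int, ...]
    mean_household_size: float

    def validate(self) -> None:
        if (self.counts[["population", "households"]] <= 0).any().any():
            raise ValueError("counts must be positive")


def generate_population(geo: GeographyMap, census_years: list[int],
                        base: float, growth: float, seed: int) -> PopulationTable:
    """National base population split across districts, geometric growth.

    Census-year counts equal ``base * (1+growth)**(y - census_years[0])``
    nationally; district shares are a fixed Dirichlet draw.  Intermediate
    years are left to the preprocessing interpolation.
    """
    if len(census_years) < 2:
        raise ValueError("need at least two census years")
    if growth <= -1.0:
        raise ValueError("growth must exceed -1")
    if base <= 0:
        raise ValueError("base population must be positive")
    census_years = sorted(int(y) for y in census_years)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    # Weights drawn per old parent district and divided by the stored split
    # shares, so population aggregates over a split lineage are consistent
    # with the geography's share bookkeeping.
    olds = list(geo.lineage)
    w_old = rng.dirichlet(np.full(len(olds), 5.0))
    w = {d: wo * geo.shares[d]
         for old, wo in zip(olds, w_old) for d in geo.lineage[old]}
    mean_hh = 5.0
    rows = []
    for y in census_years:
        nat = base * (1.0 + growth) ** (y - census_years[0])
        for d in geo.district_ids:
            pop = nat * w[d]
            rows.append((d, y, pop, pop / mean_hh))
    tab = PopulationTable(
        pd.DataFrame(rows, columns=["district", "year", "population", "households"]),
        tuple(census_years), mean_hh)
    tab.validate()
    return tab


def generate_admin_irs(truth: SyntheticTruth, households: pd.DataFrame,
                       noise: float, seed: int,
                       indicator: str = "irs") -> pd.DataFrame:
    """Administrative counts of structures sprayed, per district-year.

    ``households`` must hold annual counts (columns district, year,
    households).  Counts are true coverage times households times mean-one
    multiplicative lognormal noise, rounded; exactly zero before the
    indicator's launch year.
    """
    if indicator not in truth.indicators:
        raise ValueError(f"indicator {indicator!r} not in truth")
    launch = truth.scenario.spec(indicator).launch_year
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    pser = truth.p.sel(indicator=indicator).to_series()  # (district, year)
    hh = households[households["year"].isin(truth.years)].copy()
    pv = pser.reindex(list(zip(hh["district"], hh["year"]))).to_numpy()
    mult = np.ones(len(hh))
    if noise > 0:
        sigma = np.sqrt(np.log(1.0 + noise ** 2))
        mult = rng.lognormal(-0.5 * sigma ** 2, sigma, len(hh))
    sprayed = np.round(pv * hh["households"].to_numpy(float) * mult).astype(int)
    if launch is not None:
        sprayed[hh["year"].to_numpy() < launch] = 0
    return pd.DataFrame({"district": hh["district"].to_numpy(),
                         "year": hh["year"].to_numpy(),
                         "sprayed": sprayed})


# ---------------------------------------------------------------------------
# Survey plans and observation sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveySource:
    """One survey wave: what it measures, where, and how precisely.

    ``retro_depth`` is the number of years before the survey year for which
    birth-linked indicators are reconstructed (total covered years is
    depth + 1); the effective sample size is split evenly across those
    years.  Household-level indicators use depth 0.
    """

    source: str
    year: int
    indicators: tuple[str, ...]
    districts: tuple[str, ...] | str = "all"
    ess: float = 60.0
    retro_depth: int = 0
    design_effect: float = 1.5
    covariates: bool = False
    covariate_sd: float = 0.15

    def __post_init__(self):
        if self.ess < 1:
            raise ValueError("effective sample size must be >= 1")
        if self.design_effect < 1:
            raise ValueError("design effect must be >= 1")
        if not 0 <= self.retro_depth <= 5:
            raise ValueError("retrospective depth must be in [0, 5]")


def default_survey_plan(scenario: Scenario) -> list[SurveySource]:
    """Multi-source plan emulating a DHS/MIS/LCMS-style survey calendar."""
    birth_linked = ("anc4", "sba", "ebf", "bcg", "measles", "polio", "penta",
                    "not_underweight", "iptp2")
    household = ("itn", "irs", "itn_or_irs")
    names = {s.name for s in scenario.indicators}
    bl = tuple(i for i in birth_linked if i in names)
    hh = tuple(i for i in household if i in names)
    plan: list[SurveySource] = []
    for y in (1992, 1996, 2001, 2007):
        plan.append(SurveySource(f"dhs_{y}", y, bl, ess=75, retro_depth=4,
                                 covariates=True))
        plan.append(SurveySource(f"dhs_{y}_hh", y, hh, ess=150))
    for y in (1996, 1998, 2002, 2004, 2010):
        plan.append(SurveySource(f"lcms_{y}", y,
                                 tuple(i for i in bl if i not in ("anc4", "sba", "iptp2")),
                                 ess=60, retro_depth=4, covariates=True))
    for y in (2006, 2008, 2010):
        plan.append(SurveySource(f"mis_{y}", y, hh, ess=120))
        plan.append(SurveySource(f"mis_{y}_bl",
                                 y, tuple(i for i in ("iptp2",) if i in names),
                                 ess=60, retro_depth=4))
    for y in (2000, 2004):
        plan.append(SurveySource(f"netmark_{y}", y,
                                 tuple(i for i in ("itn",) if i in names), ess=90))
    for y in (1990, 2000, 2010):
        plan.append(SurveySource(f"census_{y}", y, (), ess=5000,
                                 covariates=True, covariate_sd=0.03))
    plan = [s for s in plan
            if s.indicators or s.covariates]
    return [s for s in plan if scenario.years[0] <= s.year <= scenario.years[1] + 2]


def _plan_districts(src: SurveySource, geo: GeographyMap) -> list[str]:
    if src.districts == "all":
        return geo.district_ids
    unknown = set(src.districts) - set(geo.district_ids)
    if unknown:
        raise ValueError(f"plan references unknown districts: {sorted(unknown)}")
    return list(src.districts)


def sample_observations(truth: SyntheticTruth, plan: list[SurveySource],
                        seed: int, exact: bool = False) -> pd.DataFrame:
    """Draw sparse noisy survey observations of the true surfaces.

    Each planned source-district-indicator cell yields one observation per
    covered year (survey year minus retro depth through the survey year),
    drawn binomially at the per-year effective sample size, with the reported
    variance ``phat*(1-phat)/n`` inflated by the design effect.  Cells whose
    draw lands on the binomial boundary (0 or n successes) are
    continuity-corrected to ``(x+0.5)/(n+1)`` — the shrinkage a design-based
    estimator needs to report a usable variance there; a truly degenerate
    truth of exactly 0 is passed through as 0 with zero variance.  With
    ``exact=True`` the observed proportion equals truth and the variance is
    the nominal binomial variance (noise-free saturated designs).
    """
    geo = truth.geo
    years = truth.years
    names = set(truth.indicators)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    pmap = geo.province_of
    pvals = truth.p.values
    ind_idx = {n: i for i, n in enumerate(truth.indicators)}
    d_idx = {d: i for i, d in enumerate(geo.district_ids)}
    y_idx = {y: i for i, y in enumerate(years)}
    frames = []
    for src in plan:
        unknown = set(src.indicators) - names
        if unknown:
            raise ValueError(f"plan references unknown indicators: {sorted(unknown)}")
        if not src.indicators:
            continue
        dlist = _plan_districts(src, geo)
        n_years = src.retro_depth + 1
        n_eff = max(src.ess / n_years, 1.0)
        ys = [src.year - b for b in range(n_years) if src.year - b in y_idx]
        if not ys:
            continue
        ii = np.repeat([ind_idx[i] for i in src.indicators], len(dlist) * len(ys))
        dd = np.tile(np.repeat([d_idx[d] for d in dlist], len(ys)),
                     len(src.indicators))
        yy = np.tile(ys, len(dlist) * len(src.indicators))
        yi = np.array([y_idx[y] for y in yy])
        p = pvals[ii, dd, yi]
        if exact:
            phat = p.copy()
            var = p * (1.0 - p) / n_eff
        else:
            n_int = max(int(round(n_eff)), 1)
            x = rng.binomial(n_int, p).astype(float)
            phat = x / n_int
            var = phat * (1.0 - phat) / n_int * src.design_effect
            # All-success cells are reported as the logit-normal moment
            # match of the Jeffreys posterior Beta(n+1/2, 1/2): informative
            # but honestly wide (a design-based estimator cannot report
            # 100% with zero variance).  All-zero cells stay at 0 with zero
            # variance; the boundary-offset rule downstream places them at
            # the representable floor with a Jeffreys-width variance.
            top = (x == n_int) & (p > 0) & (p < 1)
            if top.any():
                mu = digamma(n_int + 0.5) - digamma(0.5)
                vl = (polygamma(1, n_int + 0.5)
                      + polygamma(1, 0.5)) * src.design_effect
                pb = 1.0 / (1.0 + np.exp(-mu))
                phat[top] = pb
                var[top] = vl * (pb * (1.0 - pb)) ** 2
        dnames = np.array(geo.district_ids)[dd]
        frames.append(pd.DataFrame({
            "indicator": np.array(truth.indicators)[ii], "district": dnames,
            "province": pd.Series(dnames).map(pmap).to_numpy(), "year": yy,
            "source": src.source, "estimate": phat, "variance": var,
            "sample_size": n_eff, "flag_floor": False,
            "flag_split_adjusted": False}))
    obs = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=OBS_COLUMNS)
    dup = obs.duplicated(["indicator", "district", "year", "source"])
    if dup.any():
        raise AssertionError("duplicate observation keys generated")
    return obs


def sample_covariate_observations(truth: SyntheticTruth, plan: list[SurveySource],
                                  seed: int, exact: bool = False) -> pd.DataFrame:
    """Noisy multi-source covariate observations at survey years.

    Noise is additive on the covariate's modeling scale (logit for
    proportions, log for household size, identity for education) with a
    per-source offset, emulating sources that disagree on levels.  The
    facility-density covariate is observed once per district (a single
    facility-census year) with small noise.
    """
    geo = truth.geo
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    cov_cols = [c for c in truth.covariates.columns
                if c not in ("district", "year", "hfpc")]
    tr = truth.covariates.set_index(["district", "year"])
    rows = []
    for src in plan:
        if not src.covariates:
            continue
        if src.year not in truth.years:
            continue
        offsets = {c: (0.0 if exact else rng.normal(0.0, 0.5 * src.covariate_sd))
                   for c in cov_cols}
        sd = 0.0 if exact else src.covariate_sd
        var = max(src.covariate_sd, 0.02) ** 2
        for d in geo.district_ids:
            for c in cov_cols:
                v = float(tr.loc[(d, src.year), c])
                if c in PROPORTION_COVARIATES:
                    z = _logit(np.clip(v, 1e-4, 1 - 1e-4))
                    z = z + offsets[c] + rng.normal(0.0, sd)
                    ov = float(_invlogit(z))
                elif c == "hhsize":
                    ov = float(np.exp(np.log(v) + offsets[c] + rng.normal(0.0, sd)))
                else:
                    ov = max(v + offsets[c] + rng.normal(0.0, sd), 0.0)
                rows.append((c, d, src.year, src.source, ov, var))
    # One-off facility census for the per-capita facility covariate.
    hfpc = truth.covariates.groupby("district")["hfpc"].first()
    fy = min(max(2006, truth.years[0]), truth.years[-1])
    for d in geo.district_ids:
        v = float(hfpc[d])
        ov = v if exact else float(np.exp(np.log(v) + rng.normal(0.0, 0.05)))
        rows.append(("hfpc", d, fy, "facility_census", ov, 0.05 ** 2))
    return pd.DataFrame(rows, columns=["covariate", "district", "year",
                                       "source", "value", "variance"])


# ---------------------------------------------------------------------------
# Old-geography recoding
# ---------------------------------------------------------------------------

def recode_to_old_geography(obs: pd.DataFrame, geo: GeographyMap,
                            cutoff_year: int) -> pd.DataFrame:
    """Aggregate observations before ``cutoff_year`` to old parent districts.

    Emulates surveys sampled under the coarser pre-split geography:
    inheritor estimates are combined by precision weighting (inverse
    variance; equal weights if all variances vanish), variances combine as
    for a precision-weighted mean, sample sizes add.  Observations at or
    after the cutoff pass through untouched.
    """
    pre = obs[obs["year"] < cutoff_year]
    post = obs[obs["year"] >= cutoff_year]
    if pre.empty:
        return obs.copy()
    parent = geo.parent_of
    pmap = geo.province_of
    rows = []
    for (ind, old, y, srcname), g in pre.groupby(
            [pre["indicator"], pre["district"].map(parent), pre["year"],
             pre["source"]], sort=False):
        var = g["variance"].to_numpy(dtype=float)
        est = g["estimate"].to_numpy(dtype=float)
        if (var > 0).all():
            w = 1.0 / var
            var_c = 1.0 / w.sum()
        else:
            w = np.full(len(g), 1.0 / len(g))
            var_c = float(var.mean() / len(g))
        est_c = float((w * est).sum() / w.sum())
        prov = pmap[g["district"].iloc[0]]
        rows.append((ind, old, prov, y, srcname, est_c, var_c,
                     float(g["sample_size"].sum()), False, False))
    out = pd.concat([pd.DataFrame(rows, columns=OBS_COLUMNS), post],
                    ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def write_geography(geo: GeographyMap, path) -> None:
    parent = geo.parent_of
    df = pd.DataFrame(
        [(d, p, parent[d], geo.shares[d]) for d, p in geo.districts],
        columns=["district", "province", "parent_district", "population_share"])
    df.to_csv(path, index=False)


def read_geography(path) -> GeographyMap:
    df = pd.read_csv(path)
    provinces = tuple(pd.unique(df["province"]))
    districts = tuple(zip(df["district"], df["province"]))
    lineage: dict[str, tuple[str, ...]] = {}
    for old, g in df.groupby("parent_district", sort=False):
        lineage[str(old)] = tuple(g["district"])
    shares = dict(zip(df["district"], df["population_share"]))
    geo = GeographyMap(provinces, districts, lineage, shares)
    geo.validate()
    return geo
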