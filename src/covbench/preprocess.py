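"""Data-processing rules applied before modeling.

Four kinds of cleaning are implemented, mirroring how multi-source district
coverage data are prepared for small-area estimation:

* geometric interpolation of census household/population counts to an
  annual series;
* administrative indoor-residual-spraying coverage (structures sprayed over
  households, capped below 1);
* harmonization of observations made on an old, coarser district geography
  onto the current one, using average proportional relationships between
  parent and inheriting districts over a reference window;
* pre-launch coverage floors (0.01% before a program's assumed start) and
  the logit transform of estimates and sampling variances (delta method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .synthetic import OBS_COLUMNS, GeographyMap, PopulationTable

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "interpolate_households",
    "interpolate_population",
    "compute_irs_coverage",
    "harmonize_districts",
    "apply_prelaunch_floor",
    "to_logit",
    "preprocess_observations",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the cleaning rules; defaults are the package's choices."""

    eps: float = 1e-4               # boundary offset; equals the 0.01% floor value
    floor_value: float = 1e-4       # assumed pre-launch coverage
    floor_logit_var: float = 0.3    # logit-space variance of floor records
                                    # (the floor is an order-of-magnitude
                                    # assumption, not a measurement)
    irs_cap: float = 0.99           # cap on administrative coverage ratios
    admin_logit_var: float = 0.1    # logit-space variance for administrative data
    split_var_inflation: float = 1.5
    variance_floor_logit: float = 1e-3   # strictly-positive minimum for the GP
    zero_variance_logit: float = 0.5     # replaces zero reported variances
                                         # (e.g. all-zero survey counts)
    reference_window: tuple[int, int] = (2000, 2010)
    harmonize_cutoff: int = 2000
    floor_overrides_observed: bool = True

    def __post_init__(self):
        if not 0 < self.eps <= 0.01:
            raise ValueError("eps must be in (0, 0.01]")


def _logit(p):
    return np.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


# ---------------------------------------------------------------------------
# Households / populations
# ---------------------------------------------------------------------------

def interpolate_households(anchors: list[tuple[int, float]],
                           years: list[int] | None = None) -> pd.Series:
    """Annual counts from census anchors assuming geometric growth.

    Between consecutive anchors (a, Ha) and (b, Hb),
    ``H_t = Ha * (Hb/Ha) ** ((t-a)/(b-a))``; outside the anchor range the
    nearest segment's growth rate is extrapolated.  Anchor years are
    reproduced exactly.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    ay = [int(y) for y, _ in anchors]
    av = [float(v) for _, v in anchors]
    if any(b <= a for a, b in zip(ay, ay[1:])):
        raise ValueError("anchor years must be strictly increasing")
    if any(v <= 0 for v in av):
        raise ValueError("anchor counts must be positive")
    if years is None:
        years = list(range(ay[0], ay[-1] + 1))
    out = np.empty(len(years))
    for i, t in enumerate(years):
        if t <= ay[0]:
            a, b = 0, 1
        elif t >= ay[-1]:
            a, b = len(ay) - 2, len(ay) - 1
        else:
            b = next(j for j in range(1, len(ay)) if ay[j] >= t)
            a = b - 1
        frac = (t - ay[a]) / (ay[b] - ay[a])
        out[i] = av[a] * (av[b] / av[a]) ** frac
    return pd.Series(out, index=pd.Index(years, name="year"), name="count")


def interpolate_population(pop: PopulationTable,
                           years: list[int]) -> pd.DataFrame:
    """Per-district annual population and household counts."""
    rows = []
    for d, g in pop.counts.groupby("district", sort=False):
        anchors_p = list(zip(g["year"], g["population"]))
        anchors_h = list(zip(g["year"], g["households"]))
        p = interpolate_households(anchors_p, years)
        h = interpolate_households(anchors_h, years)
        rows.append(pd.DataFrame({"district": d, "year": years,
                                  "population": p.values,
                                  "households": h.values}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Administrative IRS coverage
# ---------------------------------------------------------------------------

def compute_irs_coverage(sprayed: pd.DataFrame, households: pd.DataFrame,
                         geo: GeographyMap,
                         config: PreprocessConfig = PreprocessConfig(),
                         indicator: str = "irs",
                         source: str = "admin") -> pd.DataFrame:
    """Coverage records from administrative spray counts.

    ``sprayed`` has columns (district, year, sprayed); ``households`` has
    (district, year, households).  The estimate is sprayed/households capped
    at ``irs_cap``; the reported proportion-space variance is chosen so that
    the delta-method logit variance equals ``admin_logit_var``.
    """
    if (sprayed["sprayed"] < 0).any():
        raise ValueError("negative sprayed counts")
    hh = households.set_index(["district", "year"])["households"]
    pmap = geo.province_of
    rows = []
    for _, r in sprayed.iterrows():
        key = (r["district"], int(r["year"]))
        if key not in hh.index:
            raise ValueError(f"no household denominator for {key}")
        ratio = float(r["sprayed"]) / float(hh.loc[key])
        if ratio > config.irs_cap:
            logger.warning("administrative IRS ratio %.3f capped at %.2f for %s",
                           ratio, config.irs_cap, key)
            ratio = config.irs_cap
        pc = np.clip(ratio, config.eps, 1 - config.eps)
        var = config.admin_logit_var * (pc * (1 - pc)) ** 2
        rows.append((indicator, r["district"], pmap.get(r["district"], ""),
                     int(r["year"]), source, ratio, var, np.nan, False, False))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


# ---------------------------------------------------------------------------
# District harmonization (old -> new geography)
# ---------------------------------------------------------------------------

def harmonize_districts(obs: pd.DataFrame, geo: GeographyMap,
                        reference_window: tuple[int, int] | None = None,
                        config: PreprocessConfig = PreprocessConfig()) -> pd.DataFrame:
    """Re-express old-geography observations on the current districts.

    For each inheriting district d of an old parent P, a ratio r_d is the
    mean over reference-window years of d's estimate divided by the
    parent-level estimate (population-share-weighted mean over inheritors
    observed that year), computed per indicator.  Observations carrying old
    district ids are replaced by one record per inheritor with estimate
    ``clip(r_d * parent estimate, 0, irs_cap... 0.99)`` and variance inflated
    by the split-inflation factor.  Inheritors with no reference data use
    r_d = 1.
    """
    window = reference_window or config.reference_window
    known = set(geo.district_ids) | set(geo.lineage)
    unknown = set(obs["district"]) - known
    if unknown:
        raise ValueError(f"observations on unknown districts: {sorted(unknown)}")

    old_mask = obs["district"].isin(geo.lineage)
    new_obs = obs[~old_mask]
    old_obs = obs[old_mask]
    if old_obs.empty:
        return obs.copy()

    # Reference ratios from new-geography data, one value per (indicator, district).
    split_kids = {d for kids in geo.split_map.values() for d in kids}
    ref = new_obs[(new_obs["year"] >= window[0]) & (new_obs["year"] <= window[1])
                  & new_obs["district"].isin(split_kids)].copy()
    # Collapse multiple sources to a precision-weighted value per cell.
    ref["_w"] = 1.0 / np.maximum(ref["variance"].to_numpy(float), 1e-12)
    ref["_we"] = ref["_w"] * ref["estimate"].to_numpy(float)
    cell = ref.groupby(["indicator", "district", "year"], as_index=False)[
        ["_w", "_we"]].sum()
    cell["estimate"] = cell["_we"] / cell["_w"]

    ratios: dict[tuple[str, str], float] = {}
    for old, kids in geo.split_map.items():
        sub = cell[cell["district"].isin(kids)]
        for ind, g in sub.groupby("indicator", sort=False):
            wide = g.pivot(index="year", columns="district", values="estimate")
            shares = np.array([geo.shares[d] for d in wide.columns])
            for d in kids:
                if d not in wide.columns:
                    continue
                vals = []
                for y, row in wide.iterrows():
                    avail = ~row.isna()
                    if not avail[d]:
                        continue
                    w = shares[avail.to_numpy()] / shares[avail.to_numpy()].sum()
                    parent_est = float((row[avail] * w).sum())
                    if parent_est > 0:
                        vals.append(float(row[d]) / parent_est)
                if vals:
                    ratios[(ind, d)] = float(np.mean(vals))

    lineage_df = pd.DataFrame(
        [(old, d) for old, kids in geo.lineage.items() for d in kids],
        columns=["_old", "_new"])
    exp = old_obs.merge(lineage_df, left_on="district", right_on="_old")
    rd = np.array([ratios.get((i, d), 1.0)
                   for i, d in zip(exp["indicator"], exp["_new"])])
    est = rd * exp["estimate"].to_numpy(float)
    n_clip = int((est > 1.0).sum())
    if n_clip:
        logger.warning("%d split-adjusted estimates exceeded 1 and were "
                       "clipped to 0.99", n_clip)
    est = np.clip(np.where(est > 1.0, 0.99, est), 0.0, None)
    adjusted = pd.DataFrame({
        "indicator": exp["indicator"], "district": exp["_new"],
        "province": exp["_new"].map(geo.province_of),
        "year": exp["year"].astype(int), "source": exp["source"],
        "estimate": est,
        "variance": exp["variance"].to_numpy(float) * config.split_var_inflation,
        "sample_size": exp["sample_size"], "flag_floor": False,
        "flag_split_adjusted": True})
    out = pd.concat([new_obs, adjusted[OBS_COLUMNS]], ignore_index=True)
    return out.sort_values(["indicator", "district", "year", "source"],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# Pre-launch floors
# ---------------------------------------------------------------------------

def apply_prelaunch_floor(obs: pd.DataFrame, launch_years: dict[str, int],
                          districts: list[str] | None = None,
                          years: list[int] | None = None,
                          geo: GeographyMap | None = None,
                          config: PreprocessConfig = PreprocessConfig()) -> pd.DataFrame:
    """Assume 0.01% coverage before each program's floor year.

    For every district-year strictly before the configured year, a floor
    record (estimate 1e-4, flagged) is inserted; by default existing
    observations in those years are replaced by the floor (the assumption is
    blanket).  Indicators without a configured year pass through unchanged.
    """
    if districts is None:
        districts = sorted(obs["district"].unique())
    if years is None:
        years = sorted(obs["year"].unique())
    pmap = geo.province_of if geo is not None else \
        dict(zip(obs["district"], obs["province"]))
    var = config.floor_logit_var * (config.floor_value * (1 - config.floor_value)) ** 2
    pieces = []
    floored = obs
    for ind, fy in launch_years.items():
        pre_years = [y for y in years if y < fy]
        if not pre_years:
            continue
        if config.floor_overrides_observed:
            drop = ((floored["indicator"] == ind) & (floored["year"] < fy))
            floored = floored[~drop]
        else:
            have = set(map(tuple, floored.loc[
                (floored["indicator"] == ind) & (floored["year"] < fy),
                ["district", "year"]].itertuples(index=False)))
        rows = []
        for d in districts:
            for y in pre_years:
                if (not config.floor_overrides_observed
                        and (d, y) in have):
                    continue
                rows.append((ind, d, pmap.get(d, ""), y, "floor",
                             config.floor_value, var, np.nan, True, False))
        pieces.append(pd.DataFrame(rows, columns=OBS_COLUMNS))
    if not pieces:
        return obs.copy()
    out = pd.concat([floored, *pieces], ignore_index=True)
    out = out.drop_duplicates(["indicator", "district", "year", "source"])
    return out.sort_values(["indicator", "district", "year", "source"],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# Logit transform
# ---------------------------------------------------------------------------

def to_logit(obs: pd.DataFrame,
             config: PreprocessConfig = PreprocessConfig()) -> pd.DataFrame:
    """Logit-transform estimates and variances (delta method).

    Proportions are clamped to [eps, 1-eps]; the logit-space variance is
    ``var_p / (p(1-p))**2`` evaluated at the clamped proportion.  Zero
    reported variances (degenerate boundary estimates such as all-zero
    counts) are replaced by ``zero_variance_logit``; all variances are kept
    above a small strictly-positive floor so the downstream Gaussian process
    sees proper data noise.
    """
    p = np.clip(obs["estimate"].to_numpy(float), config.eps, 1 - config.eps)
    var_p = obs["variance"].to_numpy(float)
    denom = (p * (1.0 - p)) ** 2
    # Zero reported variances come from all-zero counts (or degenerate
    # inputs): place them at the boundary offset with the Jeffreys-posterior
    # logit width for a zero count when the sample size is known.
    n = obs["sample_size"].to_numpy(float) if "sample_size" in obs.columns \
        else np.full(len(obs), np.nan)
    jeffreys_w = np.where(np.isfinite(n) & (n >= 1),
                          polygamma(1, 0.5) + polygamma(1, np.maximum(n, 1) + 0.5),
                          config.zero_variance_logit)
    var_l = np.where(var_p > 0, var_p / denom, jeffreys_w)
    var_l = np.maximum(var_l, config.variance_floor_logit)
    out = obs.copy()
    out["logit_estimate"] = _logit(p)
    out["logit_variance"] = var_l
    if not np.isfinite(out["logit_estimate"]).all():
        raise ValueError("non-finite logit estimates")
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def preprocess_observations(obs: pd.DataFrame, geo: GeographyMap,
                            launch_years: dict[str, int],
                            years: list[int],
                            admin_irs: pd.DataFrame | None = None,
                            households: pd.DataFrame | None = None,
                            config: PreprocessConfig = PreprocessConfig(),
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cleaning chain; returns (clean table, logit table)."""
    if admin_irs is not None:
        if households is None:
            raise ValueError("administrative IRS data require household counts")
        irs_obs = compute_irs_coverage(admin_irs, households, geo, config)
        obs = pd.concat([obs, irs_obs], ignore_index=True)
    obs = harmonize_districts(obs, geo, config.reference_window, config)
    obs = apply_prelaunch_floor(obs, launch_years, geo.district_ids, years,
                                geo, config)
    return obs, to_logit(obs, config)
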