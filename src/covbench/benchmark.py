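"""Benchmarking statistics on the draw cube.

National series are population-weighted averages of district draws taken
draw-by-draw, so national uncertainty intervals inherit the within-draw
correlation structure across districts.  Composite coverage is the
(equal-)weighted mean of a fixed basket of ten interventions.  The module
also computes a standardized socioeconomic composite and its Pearson
correlation with composite coverage, district range gaps, absolute changes
between two years, decline counts, and baseline-versus-change correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .preprocess import interpolate_population
from .synthetic import PopulationTable

logger = logging.getLogger(__name__)

__all__ = [
    "CompositeSpec", "BenchmarkReport", "DeclineCount",
    "national_series", "composite_coverage", "ses_index", "pearson_corr",
    "absolute_change", "range_gap", "count_declines", "corr_baseline_change",
    "run_benchmark",
]

SES_COMPONENTS = ["edu", "sanitation", "fuel", "elec"]


@dataclass(frozen=True)
class CompositeSpec:
    """Basket of interventions defining composite coverage."""

    components: tuple[str, ...] = (
        "itn_or_irs", "iptp2", "ebf", "penta", "bcg", "measles", "polio",
        "anc4", "sba", "not_underweight")
    weights: tuple[float, ...] | None = None   # None -> equal

    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            w = np.full(len(self.components), 1.0 / len(self.components))
        else:
            w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.components):
            raise ValueError("one weight per component required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if len(set(self.components)) != len(self.components):
            raise ValueError("component ids must be distinct")
        return w


class DeclineCount(NamedTuple):
    n_declining: int            # strictly negative point-estimate change
    n_significant: int | None   # 95% draw interval of change excludes 0


def _pop_weights(pop: PopulationTable, districts: list[str],
                 years: list[int]) -> xr.DataArray:
    annual = interpolate_population(pop, years)
    wide = annual.pivot(index="district", columns="year", values="population")
    missing = [(d, y) for d in districts for y in years
               if d not in wide.index or pd.isna(wide.loc[d, y])]
    if missing:
        raise ValueError(f"missing population for district-years: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    arr = wide.loc[districts, years].to_numpy(float)
    return xr.DataArray(arr, coords={"district": districts, "year": years},
                        dims=("district", "year"))


def _summarize_draws(da: xr.DataArray) -> pd.DataFrame:
    from .stgpr import summarize
    return summarize(da)


def national_series(cube: xr.DataArray, pop: PopulationTable) -> pd.DataFrame:
    """Population-weighted national series per indicator-year, draw-level.

    Weights are interpolated geometrically between census anchors; the
    weighted mean is taken within each draw before summarizing, so the
    national uncertainty interval reflects district co-movement.
    """
    districts = [str(d) for d in cube.coords["district"].values]
    years = [int(y) for y in cube.coords["year"].values]
    w = _pop_weights(pop, districts, years)
    nat = (cube * w).sum("district") / w.sum("district")
    return _summarize_draws(nat)


def composite_coverage(cube: xr.DataArray,
                       spec: CompositeSpec = CompositeSpec(),
                       pop: PopulationTable | None = None
                       ) -> tuple[xr.DataArray, pd.DataFrame, pd.DataFrame | None]:
    """Draw-wise weighted mean across the basket's components.

    Returns the composite draw array (district, year, draw), its district
    summaries, and — when a population table is supplied — the national
    composite summary.
    """
    have = set(str(i) for i in cube.coords["indicator"].values)
    missing = [c for c in spec.components if c not in have]
    if missing:
        raise ValueError(f"composite components missing from cube: {missing}")
    w = spec.resolved_weights()
    sel = cube.sel(indicator=list(spec.components))
    axis = sel.dims.index("indicator")
    # single dot-product accumulation for numerator and denominator, so
    # identical components reproduce their common value exactly
    vals = np.tensordot(w, sel.values, axes=([0], [axis])) / w.sum()
    rest = [d for d in sel.dims if d != "indicator"]
    comp = xr.DataArray(vals, coords={d: sel.coords[d] for d in rest},
                        dims=rest)
    comp.name = "composite"
    summary = _summarize_draws(comp)
    national = None
    if pop is not None:
        districts = [str(d) for d in comp.coords["district"].values]
        years = [int(y) for y in comp.coords["year"].values]
        pw = _pop_weights(pop, districts, years)
        nat = (comp * pw).sum("district") / pw.sum("district")
        national = _summarize_draws(nat)
    return comp, summary, national


def ses_index(covariates: pd.DataFrame,
              components: list[str] = SES_COMPONENTS) -> pd.DataFrame:
    """Socioeconomic composite: standardize components, average equally.

    Each component is z-scored across all district-years; zero-variance
    components are dropped with a warning and the weights renormalized.
    """
    missing = [c for c in components if c not in covariates.columns]
    if missing:
        raise ValueError(f"SES components missing: {missing}")
    z = []
    for c in components:
        v = covariates[c].to_numpy(float)
        sd = v.std()
        if sd == 0:
            logger.warning("SES component %r has zero variance; excluded", c)
            continue
        z.append((v - v.mean()) / sd)
    out = covariates[["district", "year"]].copy()
    # fully degenerate inputs (identical districts) score 0 everywhere
    out["ses"] = np.mean(z, axis=0) if z else 0.0
    return out


def pearson_corr(x, y) -> float:
    """Pearson correlation; NaN (with a warning) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero-variance input; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def absolute_change(summaries: pd.DataFrame, y0: int, y1: int,
                    cube: xr.DataArray | None = None,
                    indicator: str | None = None) -> pd.DataFrame:
    """Per-district change in percentage points between two years.

    When the draw cube is supplied, draw-level differences give a 95%
    interval on the change.
    """
    df = summaries
    if indicator is not None and "indicator" in df.columns:
        df = df[df["indicator"] == indicator]
    for y in (y0, y1):
        if y not in set(df["year"]):
            raise ValueError(f"year {y} not present")
    a = df[df["year"] == y0].set_index("district")["mean"]
    b = df[df["year"] == y1].set_index("district")["mean"]
    out = pd.DataFrame({"district": a.index,
                        "change_pp": 100.0 * (b - a).loc[a.index].to_numpy()})
    if cube is not None:
        da = cube
        if indicator is not None and "indicator" in da.dims:
            da = da.sel(indicator=indicator)
        diff = 100.0 * (da.sel(year=y1) - da.sel(year=y0))
        lo = diff.quantile(0.025, dim="draw", method="linear")
        hi = diff.quantile(0.975, dim="draw", method="linear")
        out["change_lower"] = lo.sel(district=out["district"].to_list()).values
        out["change_upper"] = hi.sel(district=out["district"].to_list()).values
    return out


def range_gap(summaries: pd.DataFrame, indicator: str | None, year: int
              ) -> tuple[float, str, str]:
    """Gap (pp) between best and worst district; ties by district id order."""
    df = summaries
    if indicator is not None and "indicator" in df.columns:
        df = df[df["indicator"] == indicator]
    df = df[df["year"] == year].sort_values("district")
    if len(df) < 2:
        raise ValueError("need at least two districts")
    best = df.loc[df["mean"].idxmax()]
    worst = df.loc[df["mean"].idxmin()]
    gap = 100.0 * float(best["mean"] - worst["mean"])
    return gap, str(best["district"]), str(worst["district"])


def count_declines(changes: pd.DataFrame) -> DeclineCount:
    """Districts with strictly negative change; significance-aware count too."""
    n = int((changes["change_pp"] < 0).sum())
    n_sig = None
    if {"change_lower", "change_upper"} <= set(changes.columns):
        n_sig = int((changes["change_upper"] < 0).sum())
    return DeclineCount(n, n_sig)


def corr_baseline_change(summaries: pd.DataFrame, y0: int, y1: int,
                         indicator: str | None = None) -> float:
    """Pearson r between the level at y0 and the change y0 -> y1 across districts."""
    ch = absolute_change(summaries, y0, y1, indicator=indicator)
    df = summaries
    if indicator is not None and "indicator" in df.columns:
        df = df[df["indicator"] == indicator]
    level = df[df["year"] == y0].set_index("district")["mean"]
    return pearson_corr(level.loc[ch["district"]].to_numpy(),
                        ch["change_pp"].to_numpy())


@dataclass
class BenchmarkReport:
    national: pd.DataFrame               # per indicator-year
    composite_district: pd.DataFrame
    composite_national: pd.DataFrame
    changes: pd.DataFrame                # per indicator x district
    gaps: pd.DataFrame                   # per indicator-year pair
    correlations: pd.DataFrame
    ses: pd.DataFrame
    declines: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.national.to_csv(out / "national_series.csv", index=False)
        self.composite_district.to_csv(out / "composite.csv", index=False)
        self.composite_national.to_csv(out / "composite_national.csv", index=False)
        self.changes.to_csv(out / "changes.csv", index=False)
        self.gaps.to_csv(out / "gaps.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.declines.to_csv(out / "declines.csv", index=False)
        lines = ["benchmark run summary", "---------------------"]
        for _, r in self.correlations.iterrows():
            lines.append(f"{r['name']}: r = {r['value']:.3f}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")


def run_benchmark(cube: xr.DataArray, summary: pd.DataFrame,
                  pop: PopulationTable, covariates: pd.DataFrame,
                  spec: CompositeSpec = CompositeSpec(),
                  years: tuple[int, int] | None = None,
                  ses_pooling: str = "pooled") -> BenchmarkReport:
    """Assemble the full benchmarking report from a fitted draw cube."""
    all_years = [int(y) for y in cube.coords["year"].values]
    y0, y1 = years or (all_years[0], all_years[-1])
    nat = national_series(cube, pop)
    comp, comp_sum, comp_nat = composite_coverage(cube, spec, pop)

    indicators = [str(i) for i in cube.coords["indicator"].values]
    ch_frames, gap_rows, decl_rows = [], [], []
    for ind in indicators:
        ch = absolute_change(summary, y0, y1, cube=cube, indicator=ind)
        ch.insert(0, "indicator", ind)
        ch_frames.append(ch)
        dc = count_declines(ch)
        decl_rows.append((ind, dc.n_declining, dc.n_significant))
        for y in (y0, y1):
            gap, best, worst = range_gap(summary, ind, y)
            gap_rows.append((ind, y, gap, best, worst))
    for y in (y0, y1):
        gap, best, worst = range_gap(comp_sum, None, y)
        gap_rows.append(("composite", y, gap, best, worst))
    changes = pd.concat(ch_frames, ignore_index=True)
    gaps = pd.DataFrame(gap_rows, columns=["indicator", "year", "gap_pp",
                                           "best", "worst"])
    declines = pd.DataFrame(decl_rows, columns=["indicator", "n_declining",
                                                "n_significant"])

    ses = ses_index(covariates)
    merged = comp_sum.merge(ses, on=["district", "year"])
    if ses_pooling == "pooled":
        r_ses = pearson_corr(merged["mean"], merged["ses"])
    elif ses_pooling == "by_year":
        r_ses = float(np.mean([
            pearson_corr(g["mean"], g["ses"])
            for _, g in merged.groupby("year") if len(g) >= 3]))
    else:
        raise ValueError("ses_pooling must be 'pooled' or 'by_year'")
    corr_rows = [("composite_vs_ses", r_ses)]
    for ind in indicators:
        corr_rows.append((f"baseline_vs_change_{ind}",
                          corr_baseline_change(summary, y0, y1, ind)))
    correlations = pd.DataFrame(corr_rows, columns=["name", "value"])
    return BenchmarkReport(nat, comp_sum, comp_nat, changes, gaps,
                           correlations, ses, declines,
                           extras={"composite_cube": comp})
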