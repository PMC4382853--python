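# Methods

`covbench` estimates complete district-year time series of bounded health
intervention coverage from sparse, noisy, multi-source observations, and
benchmarks districts against each other. This note documents the model, the
synthetic study design used to validate it, and the numerical and design
choices that were genuinely open.

## The estimation problem

The target is p(j, i, t) ∈ (0, 1): coverage of intervention j in district i
and year t, over a ~20-year window and ~72 districts grouped into provinces.
Observations come from household surveys (a handful of waves, each covering
some indicators, with design-inflated binomial sampling error and, for
birth-linked indicators, retrospective birth-year reconstruction that slices
the sample thin) and, for indoor residual spraying, administrative spray
counts divided by interpolated household denominators. Most district-year
cells are unobserved.

## Preprocessing

- **Household/population interpolation.** Census anchors are interpolated
  assuming geometric growth: between anchors (a, Hₐ) and (b, H_b),
  H_t = Hₐ·(H_b/Hₐ)^((t−a)/(b−a)); outside the anchor range the nearest
  segment's growth rate extrapolates.
- **Administrative IRS coverage** = structures sprayed / households, capped
  at 0.99 (administrative numerators can exceed denominators). Administrative
  records carry a fixed logit-space variance (default 0.1, configurable)
  because no design-based variance exists for them.
- **District-split harmonization.** Observations made on the old, coarser
  geography (before the split into the current districts) are re-expressed on
  the new one. For each inheriting district d of parent P, the ratio r_d is
  the mean over reference-window years (2000–2010) of d's estimate divided by
  the share-weighted parent-level estimate; pre-split records are replaced by
  one record per inheritor with estimate r_d × parent estimate (clipped to
  [0, 0.99] with a warning), variance inflated ×1.5. The mean-of-yearly-ratios
  statistic and the inflation factor are package choices; both are exposed in
  `PreprocessConfig`.
- **Pre-launch floors.** Interventions delivered by programs that did not yet
  exist are assumed at 0.01% coverage: every district-year strictly before the
  configured floor year receives a flagged record with estimate 1e-4. By
  default the assumption is blanket (observed pre-floor records are overridden);
  `floor_overrides_observed=False` keeps observed data instead. Floor records
  carry logit variance 0.3 (SD ≈ 0.55, a factor ~1.7 band): the floor is an
  order-of-magnitude assumption, not a measurement, and encoding it more
  tightly makes the model overconfident exactly where programs start.
- **Logit transform.** Estimates are clamped to [eps, 1−eps] with eps = 1e-4
  (so the floor value is the smallest representable coverage) and transformed
  with the delta method: var_logit = var_p / (p(1−p))².

### Boundary counts

Small-sample design-based estimates frequently land on the binomial boundary
(0 or n successes), where p̂(1−p̂)/n degenerates to zero. The package treats
the two boundaries asymmetrically, reflecting a real asymmetry in the domain:
pre-scale-up coverage has a genuine point mass near zero ("the program is not
there"), while nothing pins true coverage near exactly 100%.

- All-success cells are reported as the logit-normal moment match of the
  Jeffreys posterior Beta(n+½, ½): mean ψ(n+½)−ψ(½), variance
  ψ′(n+½)+ψ′(½) (≈ 4.9 for moderate n), inflated by the design effect.
- All-zero cells are reported as 0 with zero variance; the transform places
  them at the boundary offset (logit eps ≈ −9.21) with the Jeffreys
  zero-count width ψ′(½)+ψ′(n+½) — informative about "near zero", honest
  about how far above zero the truth could be.

A symmetric treatment of either kind was tried and measurably breaks interval
calibration in one direction or the other (confident wrong anchors at 99.99%,
or systematic upward bias at truly-near-zero cells).

## The three-stage model

Run independently per indicator, in logit space.

**Stage 1 — OLS.** logit(Ind)_{i,k,t} = β₀ + β₁t + β₂elec_{i,t} +
β₃fhead_{i,t} + β₄hhsize_{i,t} + β₅edu_{i,t} + β₆wall_{i,t} + β₇HFPC_i +
β₈Ind_{k,t} + ε, with t centred at 2000 and Ind_{k,t} the province-level
series of the same indicator. The regression is unweighted (a
precision-weighted variant exists behind a flag). Rank-deficient designs drop
collinear columns via pivoted QR with a warning naming them.

**Stage 2 — spatial-temporal residual smoothing.** The smoothed residual at a
cell is the weighted mean of observed stage-1 residuals, with weight =
spatial factor × tricube temporal factor: spatial factor 1 in the same
district, ζ = 0.5 for another district of the same province, 0 across
provinces; temporal factor (1 − (|Δt|/(λ+1))³)³ for |Δt| ≤ λ = 10 years.
Cells with no in-support residuals keep the stage-1 prediction. The smoothed
surface (prediction + smoothed residual) is the mean function of stage 3.

**Stage 3 — Gaussian process regression.** Districts are independent GPs over
years conditional on the stage-2 mean (spatial pooling happens only in stage
2). Covariance is Matérn; ν = 3/2 by default, with ν ∈ {1/2, 3/2, 5/2}
closed forms implemented. Observation noise is the heteroskedastic logit
variance from preprocessing; multiple sources in the same district-year enter
as separate observations. The amplitude σ is estimated per indicator as the
SD of the data residuals around the stage-2 mean, floored at 0.1.

The **length-scale defaults to ρ = 5 years**. With annual grids and vertical
programs whose true logit coverage moves more than one unit per year during
scale-up, a 10-year length-scale transports tight late-era observations half a
decade back and collapses posterior width in years with weak data; empirical
95%-UI coverage of truth improved from ~0.82 to ~0.93 (with slightly lower
MAE) when shortening ρ from 10 to 5 under the default study conditions.
ρ is in `GPRConfig` for users whose processes move slower.

**Draws and summaries.** 1,000 (configurable) multivariate-normal draws per
district from the posterior, inverse-logit transformed (logits clipped to
±30, so draws are strictly inside (0,1)); means and 2.5/97.5 percentiles
(linear-interpolation rule) summarize. Draw streams are keyed on
(seed, indicator index, district index), so cubes are byte-reproducible and
insensitive to execution order. Cholesky factorizations add jitter 1e-8,
escalating ×10 to at most 1e-2 before failing with the district named.

## Covariate completion

Each covariate is completed independently on a transformed scale (logit for
proportions, log for household size, identity for education): (1) a linear
mixed-effects model with a natural cubic spline in year (one interior knot at
2000; the basis is the standard truncated-power construction, linear beyond
the boundary knots) as fixed effects and a district random intercept and
slope, fit by REML (ML retry, then fixed-effects OLS fallback on convergence
failure); (2) a per-district GP around that mean (same Matérn machinery,
fixed amplitude 0.3 on the transformed scale). Districts with no data get the
fixed-effects curve. Health facilities per capita is time-constant (observed
in one facility-census year) and bypasses the model. Province-level indicator
series — the β₈ covariate — are produced by the same two-step model after
precision-weighted aggregation of district logit observations to
province-year-source cells; survey waves lacking district identifiers
contribute directly at province level.

## Benchmarking layer

National series are population-weighted means of district values taken
draw-by-draw (weights geometrically interpolated between censuses), so
national intervals inherit cross-district co-movement within draws; how
national uncertainty is formed is a package choice. Composite coverage is the
weighted (default equal) draw-wise mean of a fixed ten-intervention basket;
the weighted mean is normalized by the floating-point weight sum so that
all-components-at-100% yields exactly 100%. The socioeconomic composite
z-scores four components (adult education, improved sanitation, improved
cooking fuel, electricity) across district-years and averages them equally —
the aggregation is a package choice; a principal-component variant is out of
scope. Pearson correlation between composite coverage and SES is pooled
across district-years by default (`ses_pooling="by_year"` averages per-year
correlations instead). "Decline" counts districts with strictly negative
point-estimate change; a significance-aware count (draw-level 95% interval of
the change excluding zero) is reported alongside.

## Synthetic study design

The generator produces the study conditions the model assumes, with known
truth:

- **Geography:** 72 districts in 9 provinces; 15 "old" districts each split
  into two inheritors (within one province) with random population shares —
  pre-2000 observations are aggregated to the old geography by precision
  weighting before the pipeline re-harmonizes them.
- **Truth:** generated *from* the stage-1 functional form — known β on known
  covariate surfaces plus province AR(1) shocks (SD 0.15, lag-1 coefficient
  0.85) and district shocks (random intercept SD 0.3, indicator-specific
  trend deviations, AR(1) SD 0.2) in logit space, then inverse-logit.
  Vertical indicators (4 malaria-control, pentavalent) are clamped to exactly
  1e-4 before their launch year; their intercepts sit near logit(1e-4) minus
  the typical covariate contribution with a large loading (13–14) on a
  logistic province "program-intensity" ramp, so true coverage rises
  *continuously* out of the floor — hidden discontinuities with no data
  nearby are not a feature of real scale-ups. Routine indicators follow
  linear logit trends: antenatal care and skilled birth attendance decline
  with convergence (high-baseline districts decline most), exclusive
  breastfeeding scales up, immunizations stay high with polio stagnant and
  dispersed.
- **Observations:** a DHS/MIS/LCMS-style calendar (4 national surveys with
  4-year retrospective birth-year depth, malaria surveys from 2006, living
  conditions surveys, two net-ownership surveys, three censuses measuring
  covariates precisely); binomial sampling at the per-year effective sample
  size (survey ESS split across retrospective years), design effect 1.5,
  boundary counts handled as above. Covariate observations get additive noise
  on the modeling scale plus per-source level offsets (sources disagree).
  Administrative spray counts are truth × households × mean-one lognormal
  noise (20% relative error), zero before launch.

What the generator does **not** emulate: real survey microdata layouts and
multistage weighting, cluster-level geography, non-sampling bias (recall,
social desirability), indicator-specific biology, or migration. Passing tests
therefore show that the pipeline recovers the kind of structure it assumes,
at realistic sparsity and noise — not that those assumptions hold in any
particular country's data.

## Validation performed by the test suite

- Stage-1 coefficients recovered to 1e-6 on noiseless data (normal-equations
  oracle agreement); GP posterior equal to an explicit dense solve to 1e-8 in
  sparse districts.
- Over 50 seeded replicates of the default scenario (200 draws for speed),
  empirical 95%-UI coverage of true district-year values lies in [85%, 99%]
  (typically ~93%), and mean absolute error improves monotonically across
  stages (GP ≤ OLS+ST ≤ OLS).
- Conservation identities (composite of full coverage = 100% exactly;
  equal-population national = simple mean; split harmonization conserves
  parent-level coverage absent clipping), byte-level reproducibility given a
  seed, floor behavior (pre-1997 malaria cells at 0.01%, final estimates
  below 1%), and the noiseless-saturated identity (final estimates within
  0.01 of truth).

Problem sizes used in tests and the acceptance script: the full default
scenario (12 × 72 × 21 cells) for calibration replicates; 12-district
geographies for unit-level and identity checks; 200 draws in replicated runs
and 1,000 in single headline runs.

## Known limitations

- The GP treats the stage-2 mean function as known; its uncertainty is not
  propagated. Interval coverage dips for indicators observed almost entirely
  through zero counts during early scale-up (the Gaussian likelihood cannot
  represent the one-sided information in replicated zero counts, which
  stack as if independent).
- Stage-1 uses completed covariates as plug-in values; covariate posterior
  uncertainty is not propagated either.
- Districts are conditionally independent in stage 3; no joint spatial GP.
- No hyperparameter optimization: kernel parameters are defaults/configuration.
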