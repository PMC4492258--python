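# Methods

This note records the statistical model, the conventions and defaults the
package commits to, and what the bundled simulator does and does not
emulate.

## The period grid and alignment

All analysis happens on contiguous half-open 14-day intervals whose centre
day (interval start + 7 days) is a Wednesday, spaced 14 days apart. A
14-day interval has no single central day; defining the centre as
start + 7 days is a half-day convention chosen because it is deterministic
and makes the tiling gap-free. The anchor Wednesday is configurable (the
helper default is the first Wednesday on/after the earliest measurement).
A 24-hr sample is assigned to the unique interval containing its start
date — a sample falling on a boundary day follows the half-open
convention. A 14-day sample is assigned to the interval it overlaps most,
and dropped if the best overlap is under 10 days (configurable via
`AggregationPolicy.min_overlap_days`); two adjacent periods can each
overlap a 14-day window by at most 7 days, so assignments above the
threshold are unique.

## Harmonization

Within each site × period cell, an assigned 2-week integrated sample is
used directly; otherwise the arithmetic mean of the assigned 24-hr samples
is used provided at least `min_daily_per_period` (default 2) are present,
else the cell is missing. The default of 2 keeps every-6th-day schedules
(2–3 samples per period) while discarding isolated single days; the
completeness rule is an assumption, exposed in the policy object. A cell
holding both durations is an error by default (`prefer_integrated`
resolves it in favour of the integrated sample) — a single network-site
should never mix them. Transforms: ln(x + 1) by default, or ln(x + c) with
c = 0.1 × the mean observed value of the (single-pollutant) panel,
computed over the whole panel rather than per site. Both are exactly
invertible from the stored constant.

## Comparability statistics

Co-located monitors are paired period-by-period on the transformed scale.
Agreement is summarized by Pearson r, the ordinary-least-squares line of
y on x (matching how such pairs are usually plotted; an errors-in-variables
Deming option exists but is not the default), and the mean difference. A
pure multiplicative method bias m appears, for concentrations large
relative to the transform constant, as slope 1 and intercept ln m; an
additive bias (e.g. a blank-correction difference) bends the intercept
negative while leaving correlation high.

Smoothed temporal patterns pool all observed (period, value) points across
a site subset and fit a deterministic local-linear smoother with tri-cube
weights; bandwidth is in periods (default 6). Local-linear with tri-cube
was chosen as the simplest smoother that is linear in the data,
interpolates as bandwidth → 1 period, and handles unequal point densities;
the family and bandwidth are recorded in every output. Evaluation outside
the observed period range returns missing rather than extrapolating; a
window containing fewer than two distinct abscissae degenerates to the
weighted mean.

## Trend extraction

The shared trend is the leading right singular vector of the row-centred
long-series panel. Row-centring (site means absorbed by the long-term-mean
part of the model) separates the mean surface from the trend cleanly; a
consequence is that any constant component of the true seasonal function
is unidentifiable and the extracted trend is the centred one. "Long
series" eligibility is ≥ 50 % of periods observed (configurable);
at least two eligible sites are required. Missing cells are initialized
with column means (falling back to row means, then the grand mean) and
refined by iterating {row-centre, rank-1 SVD reconstruction, refill
originally-missing cells} until the largest imputed-cell change falls
below 1e-6 or 100 iterations (non-convergence returns the current answer
with a flag and warning). On a complete panel the loop is a no-op, so the
result equals the direct SVD. The sign indeterminacy is resolved by
requiring non-negative correlation with the panel's column means; negating
the input panel therefore negates the trend. The trend is smoothed with
the same local-linear smoother and then re-normalized to unit L2 norm
(smooth-then-normalize order).

## The simplified model

y(s,t) = x(s)ᵀγ₀ + A(s) f(t) + ε(s,t), fitted by pooled ordinary least
squares with homoscedastic independent residuals. The absence of any
spatial dependence structure is the point of the simplification: it is
what lets a design of a few fixed sites plus many one-to-three-sample
home-outdoor snapshots be fitted at all, with the snapshots entering as
ordinary rows (per-site intercepts for them would be unidentifiable; the
covariates carry all spatial mean structure). Both amplitude modes are
provided — constant θ and covariate-driven x(s)ᵀγ₁ — because either can be
appropriate depending on how strongly the seasonal amplitude varies over
space; a model-comparison sanity check (constant-mode residual variance
exceeds covariate-mode when the true amplitude varies) is in the test
suite. σ̂² uses the (n − p) divisor; rank-deficient designs are rejected
with the collinear columns named. Long-term-average predictions are
x(s)ᵀγ̂₀ + Â(s)·mean(f) over the averaging window, with a plug-in standard
error from the coefficient covariance (it quantifies mean-surface
uncertainty, not a new observation). Leave-one-site-out cross-validation
refits the regression per fold with the trend held fixed (the trend comes
from the fixed sites and is nearly unchanged by dropping one site) and
scores site-level means over exactly the periods each site observed, so
sites observed in different seasons are compared fairly.

## Feasibility rules

The decision among (1) combine-all, (3) surrogate-trend, and (2)
study-only-simplified is evaluated in that order, falling through to NONE.
The numeric thresholds — ≥ 10 regulatory sites, median co-located r ≥ 0.8,
median surrogate-trend r ≥ 0.9, ≥ 3 fixed sites — are this package's
codification of what is inherently a judgment call; they are defaults
chosen so that sparse component networks with moderate co-location
agreement and poor trend agreement land on the simplified study-only
model, and every threshold is configurable and echoed in the report.
Medians (not means) aggregate per-group correlations so one bad
co-location cannot veto a branch; an empty evidence list fails its branch
explicitly with "no evidence".

## The synthetic-data generator

The generator is the package's study system. Ground truth is
log C(s,t) = x(s)ᵀγ₀ + (x(s)ᵀγ₁) f(t) + ε(s,t) + η(s): covariate-driven
long-term means, one smooth annual seasonal trend with spatially varying
amplitude, per-period zero-mean Gaussian residual fields with exponential
spatial covariance (sill and range configurable; exponential was chosen as
the simplest standard family for "spatially dependent, temporally
independent" residuals), and a per-location nugget. Covariates are one
standardized distance-to-centre predictor plus iid standard normals; study
and urban regulatory sites cluster near the region centre while IMPROVE
sites sit on a peripheral ring, reproducing the geometry that makes rural
monitors poor proxies for participant homes.

Sampling designs: fixed study sites take one 14-day sample per period;
rotating home sites take 1–3 samples at random periods with
P(1,2,3) = (0.35, 0.5, 0.15) — a distribution chosen to give the design's
1.8 samples-per-site average and configurable; regulatory sites take 24-hr
samples every 3rd (core CSN, IMPROVE) or 6th (supplemental CSN) day.
Region presets carry the six study cities' per-network site counts (e.g.
Los Angeles: 3 + 3 CSN, 8 IMPROVE, 7 fixed, 116 home = 137 sites).

Measurement distortions per network: multiplicative and additive bias on
the concentration scale (the additive term applied after exponentiation so
protocol differences show up as negative log-scale intercepts), mean-one
log-normal sampler noise with a given CV, and extra day-to-day CV for
24-hr samples. The 24-hr values vary around the containing period's latent
mean rather than a daily latent process; this reproduces the
aggregation-mismatch phenomenon between 2-week and every-Nth-day sampling
without modeling daily meteorology, and is the main respect in which the
simulator is less rich than real data (no day-to-day autocorrelation, no
shared meteorological events across sites within a period, no seasonal
heteroscedasticity, no detection limits). Passing tests therefore
demonstrate correctness of the pipeline's algebra and its statistical
calibration under the assumed structure, not robustness to real-data
pathologies. Co-located sites share coordinates, covariates and the
location-level random draws, so zero-distortion co-located series coincide
exactly and paired comparisons isolate the configured method effects.

Randomness: one study seed fans out to stage streams via
`SeedSequence([seed, code])` (1 = sites, 2 = field, 3 = sampling), making
every artifact byte-reproducible from config + seed; the pipeline manifest
records SHA-256 hashes of all artifacts to make this checkable.

## Problem sizes

Defaults used by the pipeline demo and the test suite — 40 two-week
periods (about 18 months), regions of ~60 km with up to ~140 sites,
replicate counts of 20–100 for recovery checks and 10,000 simulated sites
for design-statistics estimates — are sized so that Monte-Carlo error is
small relative to the effects being checked while the whole suite runs in
seconds on a laptop.

## Known limitations

- Only the simplified (no-spatial-dependence) estimator is implemented;
  the full spatiotemporal model with spatially correlated random effects
  and kriging-based prediction exists here only as the simulator's truth,
  not as a fitted model.
- The LOSO trend is not re-estimated per fold; for very small fixed-site
  networks this slightly understates cross-validation uncertainty.
- No calibration models between protocols are fitted; the compatibility
  module quantifies disagreement but does not correct it.
- Single-pollutant panels: surrogate-trend checks compare trends extracted
  from separately harmonized panels rather than joint multi-pollutant
  fits.
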