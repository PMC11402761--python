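# Methods

This note records the modelling choices behind `sanibound`: what each
stage assumes, which defaults matter, what the synthetic generator does
and does not emulate, and the numerical conventions.

## The index

The weighted-arithmetic GWQI condenses an 11-parameter chemistry sample
(EC, Na⁺, K⁺, total hardness, Fe²⁺, TDS, pH, Cl⁻, HCO₃⁻, Mg²⁺, Ca²⁺)
into one number: per parameter, a quality rating `qᵢ = 100·Cᵢ/Sᵢ`
against the WHO guideline standard `Sᵢ`, weighted by a relative weight
`Wᵢ` and summed. Conventions:

- **Weights.** The packaged table carries the published relative
  weights verbatim; they sum to 1.0036 rather than 1 (iron dominates at
  0.920, consistent with raw weights proportional to `1/Sᵢ`). By
  default the index uses them as printed so published numbers are
  reproduced exactly; `renormalize=True` divides by the sum. Raw
  weights are not published, so the table accepts `Wᵢ` directly and
  does not guess `wᵢ`.
- **pH.** Its guideline is a range (6.5–8.5) but the rating formula
  admits a single denominator; the upper bound 8.5 is used by default
  (the conservative denominator) and can be overridden via
  `GuidelineTable.with_standard("pH", ...)`.
- **Classes.** The published class bounds use strict inequalities that
  leave 50, 100, 200 and 300 unassigned; we close each interval on the
  left ([0,50) excellent, [50,100) good, [100,200) poor, [200,300)
  very poor, [300,∞) unsuitable) so classification is total and
  deterministic.
- **Partial samples.** Wells missing some parameters get an index over
  the available subset with weights *not* renormalized (the plain-sum
  definition); a warning lists what is missing. Structural-model noise
  can produce index values below 0; these carry no quality class and
  are excluded from class tallies.

## Regression and selection

Ordinary least squares (via statsmodels) with standard errors from the
unbiased residual variance, `t = β/SE`, and two-sided p-values.
Stepwise selection is the t-based variant: forward entry of the
candidate with the smallest p-value below `p_enter`, backward removal
of any retained predictor above `p_remove`, iterated to a fixed point.
Defaults `p_enter = 0.05`, `p_remove = 0.10` (the common statistical-
package convention; the source names the method but not thresholds).
Ties on entry p-values break by larger |t|, then candidate order. Once
a fit becomes numerically exact (1 − R² < 1e-12) no further entries are
attempted, since entry p-values are then meaningless. Correlation
p-values come from the t transform of Pearson r; constant variables
yield *undefined* (NaN) correlations, never silent zeros.

The train/validation split is a seeded uniform partition; the training
size is `round(n·fraction)` with half-away-from-zero rounding. The
source text says 80/20 while its validation table holds 28 of 112 wells
(25 %); both are reachable through the `fraction` parameter. Validation
R² is the squared Pearson correlation between measured and predicted
index values (the convention matching the published 0.85); the
`about_identity` flag switches to `1 − SSres/SStot` about the y = x
line, which additionally penalizes bias.

## Boundary inversion

The fitted forward model `GWQI = β₀ + β_Tr·Tr + β_d·W_depth +
β_L·L_pw` is solved for `L_pw` at a nominal index value (default 25;
it is an ordinary parameter, so boundaries for other targets, e.g. the
excellent/good edge at 50, are equally available). Inversion always
uses the full-precision coefficients, which makes the round-trip
identity exact to 1e-10 — substituting the computed boundary back into
the forward model returns the nominal index. The published 3-decimal
equation is a *display* surface: `rounded_equation()` rounds the
inverse coefficients first and derives the nominal constant from the
rounded values, which is how the printed constant (330.889, vs 330.882
at full precision) arises. Negative raw boundaries (deep wells in
tight aquifers) are clipped to 0 by default — a distance cannot be
negative — with clip events logged.

## Mapping

Wells are projected to metres either through the built-in WGS84 UTM
transform (series implementation, forward/inverse round-trip below
1e-9°; Yaoundé falls in zone 32N) or passed through for synthetic
fields already in a local metric frame. Interpolation is inverse
distance weighting with power 2 over the 12 nearest neighbours and no
search radius by default — the common GIS defaults; the source
specifies none. A target within 1e-9 m of a sample returns the sample
value exactly; duplicate sample locations merge when their values
agree and are an error otherwise. The grid uses 50 m cells, matching
the published resolution. Classification is equal-interval over the
span of valid cells — the published R1–R5 ranges have equal ~66 m
widths, which identifies the scheme — with exact real edges for the
assignment and integer display ranges rounded so consecutive ranges
abut (39–105, 106–171, …). Rasters serialize as ESRI ASCII grids;
GeoTIFF export is out of scope.

## Synthetic well fields

The generator exists so that every pipeline stage can be exercised at
known truth. Two modes share one construction:

- **Correlation mode** targets the published six-variable correlation
  matrix (GWQI, elevation, latrine distance, depth, transmissivity,
  age). Sampling is NORTA: a Gaussian copula with lower-truncated
  normal marginals. Floors express physics — distance ≥ 0 m,
  depth ≥ 0.5 m, transmissivity ≥ 0.01 m²/day, age ≥ 0 yr — and each
  marginal's parent normal is moment-matched so the *delivered* mean
  and sd equal the targets (estimated from the 28-well fixture, the
  only published well-level data). Because the copula transform
  attenuates correlations, the latent matrix is calibrated by a damped
  fixed-point iteration against large generated fields (its own fixed
  seed; deterministic and cached). A naive alternative — resampling
  rows that violate the floors — was measured to bias the key
  correlations by 0.05–0.08 and shrink the distance sd by ~25 %, which
  is why the copula construction is used. Targets are met to about
  ±0.01 at n = 10⁴. Any requested target matrix is first repaired to
  the nearest positive semi-definite correlation matrix (Higham-style
  alternating projections); the published matrix is already PD, so the
  repair distance is zero there.
- **Structural mode** draws the five covariates the same way (5×5
  sub-matrix) and then generates
  `GWQI = 157.022 + 3.873·Tr − 2.332·W_depth − 0.399·L_pw + N(0, σ)`,
  with σ = 27 index units by default, which puts the fitted R² near
  0.80 for the fixture-based covariate covariance (the published fit
  reports 0.796; the realized mean across replicates here is ≈ 0.78).

Coordinates are placed uniformly over a 15 km × 15 km local frame,
roughly the extent of the mapped urban area. What the generator does
*not* emulate: spatial autocorrelation of transmissivity or depth (the
source maps interpolate point wells, not a random field), measurement
error in the covariates, non-Gaussian index noise, and any
well-to-well clustering. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the assumed model, not
robustness of the published equation to field realities.

A note on selection frequencies: with σ = 27 the transmissivity term's
true t-statistic is about 2 (the published table itself shows t = 1.985,
p = 0.050), so in replicated experiments it is selected in roughly
50–80 % of runs — an inherent property of a borderline predictor, not
an implementation defect. Depth and distance are selected in > 90 % of
replicates, elevation and age in < 15 %.

The chemistry synthesizer inverts the index: concentrations
`Cᵢ = (g/100)·Sᵢ·(1+δᵢ)` with perturbations constrained to zero
weighted mean reproduce a target index `g` to 1e-9 under renormalized
weights.

## Problem sizes and determinism

Default experiment sizes: n = 112 wells (the study size) for
structural simulations, 500 replicates for coefficient-recovery
summaries, n = 10,000 for correlation-target checks, and pipeline maps
of a few hundred cells; the full test suite and the acceptance script
each run in well under a minute on one CPU. Every stochastic component
takes an explicit seed; fixed seeds give byte-identical CSV and raster
outputs, and the pipeline writes a manifest recording all parameters.

## Known limitations

- The boundary is a regression inversion, not contaminant-transport
  physics; it inherits every limitation of the linear model, including
  extrapolation outside the sampled covariate ranges (clipping hides
  the most obvious symptom).
- The full 112-well dataset is unpublished; fixtures carry only the
  28-well validation subset, so published whole-area statistics (map
  range 39–370 m, mean 215 m, class proportions) cannot be recomputed
  here and are covered by property-based checks of the machinery
  instead.
- The stepwise pipeline occasionally retains a noise covariate (a
  false positive at the 5 % entry level); the inversion stage then
  refits on the admissible hydro terms (Tr, depth, distance) before
  inverting, with a logged warning.
- Pairwise-complete correlation can yield a non-PSD matrix under heavy
  missingness; downstream synthetic use repairs it explicitly.
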