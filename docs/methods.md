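# Methods

This note records the models the package implements, the defaults and why,
the numerical choices, and what the synthetic generator does and does not
emulate.

## Demography

Growth is measured as the continuous annual rate
`lambda = ln(hd1/hd0)/(t1-t0)`.  This form is independent of the density
level — scaling both densities leaves lambda unchanged — so correlations of
lambda with initial density are a property of the data, not of the
definition.  The geometric alternative `(hd1/hd0)^(1/dt) - 1` shares that
property and is available via `form="geometric"`; over census-scale growth
the two differ only by a smooth monotone rescaling, and the package keeps
the continuous form as the default because it composes additively across
intervals.  `advance_density` is the exact inverse of `growth_rate`, and the
synthetic generator advances populations through it, which is why noiseless
round trips in the tests are exact rather than approximate.

Non-climate predictors use the transforms conventional for their
distributions: density is `log10` transformed (county densities are heavily
right-skewed), income is z-scored within each census so censuses with
incompatible income questions remain comparable, crop-and-pasture fraction
of county area is arc-sine-square-root transformed, and waterway distance is
square-root transformed.  All z-scores use the sample SD (n−1): counties are
treated as a sample, and the choice only rescales all z-scores by a common
factor.  A census with no usable income data is filled by time-weighted
interpolation between the nearest bracketing censuses (weights proportional
to temporal proximity, e.g. 0.333/0.667 for a year one third of the way
between its neighbours); counties that still lack a value are dropped from
that interval's regression with a logged warning rather than imputed.

Counties lacking a population figure at any census are excluded up front:
growth rates across a century are only comparable on a constant county set.

## Climate

Four variables per county and 20-year horizon: annual mean temperature,
temperature seasonality (SD of the 12 monthly means), annual precipitation,
precipitation seasonality (SD of the 12 monthly totals).  Seasonality uses
the sample SD (n−1) by default with a population-SD switch (`ddof=0`); with
12 fixed months the two differ by the constant factor sqrt(12/11) ≈ 1.04 and
no downstream conclusion depends on the choice.  Yearly values are averaged
over each horizon, and each census year maps to the horizon ending at it —
except the first census of the record, which reuses the earliest available
horizon (1900 → 1901–1920), since no instrumental data precede the century.
Consequently the first two censuses share climate conditions: exposure
means still differ (populations differ) but the first census's area mean
would duplicate the second's, so it is flagged invalid rather than
reported.

Interpolation to county centroids is inverse distance weighting over all
stations with power 2 (configurable).  Power and neighbourhood have no
effect when stations coincide with the interpolation points, which the
tests exploit; the result is always bounded by the station extremes and
exact at stations.  Distances are planar Euclidean in the input coordinate
units, matching the degree-denominated bandwidths used for the regressions;
a haversine option exists for geographic data where curvature matters.

For a growth interval `(t0, t1)` the climate predictors are the normals of
the horizon ending at `t1` (the interval's own 20 years of weather), while
the non-climate predictors are measured at `t0` (initial conditions).

## Exposure accounting

`exposure_mean` is the population-weighted mean, `area_mean` the unweighted
county mean; deltas are taken between configurable endpoint censuses
(default: second to last, since the first shares the second's climate).
The amplification ratio is their quotient and is reported as NaN (flagged
"undefined" in reports) when the area-mean change is zero — a legitimate
outcome under constant climate, not an error.  Exactly-uniform weights
short-circuit to the unweighted mean so the identity
`exposure_mean == area_mean` holds bit-exactly in that case instead of to
rounding error.

## Niche surface

Populations are binned on a half-open 2-D grid (last cell closed) spanning
the observed climate range plus a 2 % margin, 50×50 cells by default; bin
totals conserve population exactly.  The smoothed surface is classical
LOESS on `log10(1 + pop)`: at each cell center a full quadratic in the two
range-normalized climate coordinates is fitted by weighted least squares to
the nearest `ceil(alpha*N)` cells with tricube weights and evaluated at the
center (`alpha = 0.3`, degree 2).  The `+1` keeps empty cells finite; range
normalization makes the two climate units commensurable in the distance
metric.  Cells with too few positively weighted neighbours for the
quadratic fall back to linear, then to a weighted mean, with a warning.

Peaks are strict local maxima over the 8-neighbourhood, interior cells
only (a boundary maximum of a monotone surface is a grid artifact, not a
niche mode), thinned greedily so no two peaks are within `min_separation`
cells (the higher peak wins), and tracked across censuses by
nearest-neighbour matching in normalized climate space within a radius;
an unmatched peak starts a new lineage, logged.  Per census, a lineage's
abundance is the raw population within the tracking radius of its matched
peak.  Binning resolution, alpha, separation and radius are all
configurable; the defaults were chosen once for the default grid and the
surface shape is insensitive to moderate changes in alpha.

## Geographically weighted regression

The local estimator is exact weighted least squares,
`beta_i = (X'W_iX)^{-1}X'W_i y`, with bi-square weights
`(1-(d/b_i)^2)^2` (zero from the bandwidth outward) and adaptive bandwidth
`b_i` = distance to the `k`-th nearest *other* county,
`k = ceil(f(n-1))` — "share of neighbouring counties" is read as excluding
the focal one.  The box ("uniform") kernel closes its support at `d = b` so
that fraction 1 reproduces global OLS exactly, which the tests use as a
limit check.

Diagnostics follow the standard nonparametric-regression account: the hat
diagonal at location i is `w_i(0) x_i'(X'W_iX)^{-1}x_i`, effective
parameters `enp = tr(S)` (the sum of those diagonals), and

    AICc = n ln(RSS/n) + n ln(2 pi) + n (n + enp) / (n - 2 - enp),

the small-sample form for models with non-integer effective dimension; the
variant is recorded in the fit metadata.  AICc is undefined when
`n <= enp + 2` — on very small county sets with a 9-column design this is a
hard domain error, which is why the smallest usable lattice for the full
model suite is about 10×10.  Akaike weights are `exp(-Delta/2)` normalized.

A local design whose cross-product matrix has condition number above 1e10
raises a collinearity error carrying the location; the fit retries that
location along a widening fallback schedule of fractions (default
0.3 → 0.45 → 0.5, mirroring the widened bandwidths used for the
non-climate-only models in the early intervals, where the socio-economic
predictors are most spatially collinear).  No ridge term is added: that
would change the estimator itself.

Standardized coefficients come from z-scoring predictors and response over
the interval's counties *globally* (not per local fit), so |stdbeta| is
comparable across counties; the scaling record makes raw-scale coefficients
recoverable exactly.  Relative importance gives each county one vote for
its max-|stdbeta| predictor; ties (measure-zero in continuous data) go to
the first predictor in the canonical column order and are counted and
logged.  Vote shares are computed in exact rational arithmetic and sum to
exactly 1.

The model suite per interval is: global OLS on all 8 predictors, GWR on the
4 climate predictors, GWR on the 4 non-climate predictors (with the
per-interval fraction overrides 0.5/0.5/0.45 for the first three
intervals), and GWR on all 8, compared by AICc and Akaike weights.

## Synthetic data

The generator is the package's stand-in for census and gridded-climate
archives.  It emulates: a unit-spaced planar county lattice (land area 1);
monthly station series `base + gx*x + gy*y + A sin(2 pi m/12) + trend*(year
- start)` (precipitation analogous, floored at 0); log-normal incomes,
Beta-distributed agricultural fractions, and waterway distance to the
western lattice edge; and censuses advanced from log-normal initial
densities under `lambda = sum_j beta_j(u,v) z_j + eps`, with
constant/linear/Gaussian coefficient surfaces recorded as ground truth and
`eps ~ N(0, noise_sd)`.  Predictor columns are z-scored before the
coefficients apply, so recorded truth lives on the same standardized scale
the analysis estimates.

Default study conditions: 30×30 lattice (900 counties — the same order as a
continental county set after completeness filtering), six censuses
1900–2000, residual growth SD 0.01/yr (the scale of county-level census
residuals), a 0.003 °C/yr temperature drift (≈0.24 °C over the 80-year
reporting window, matching the observed 20th-century continental-U.S.
warming), and coefficient magnitudes that put county growth on the
~0.01/yr scale.  The default climate additionally carries per-station
"microclimate" offsets (SD 1 °C / 6 mm) and spatial gradients in seasonal
amplitude.  This texture matters: with a purely affine climate field the
four derived climate variables are linear functions of the two coordinates,
so every kernel neighbourhood's design matrix is rank deficient and GWR is
degenerate *by construction*, not numerically.  Interpolated real climate
is never exactly affine.  The micro-offset parameters default to zero in
`ClimateSpec` itself, so the closed-form field examples hold exactly;
the default `SyntheticConfig` switches them on.

Scenario builders fix the conditions for specific checks: the
*amplification* scenario (zero trend, `lambda_i = c T_i`, equal initial
populations, default sensitivity 0.002 /yr/°C) attaches the analytic
exposure trajectory computed from the generating rule; the *gradient*
scenario uses unit-norm gradient directions with a common span of 0.10 so
every coefficient surface has the same spatial SD and is equally
recoverable; the *model-selection* scenario combines spatially varying
climate effects with constant non-climate effects and holds incomes fixed
across censuses so the generating model matches the fitted one.

What the generator does **not** emulate: real geography and boundary
changes, spatially autocorrelated growth noise, measurement error in the
censuses, non-stationary climate variance, or correlation between
covariates and climate beyond what the coefficient surfaces induce.
Passing tests therefore demonstrate correctness of the estimators and
accounting on data of known structure — not that real census data satisfy
the generating assumptions.

## Problem sizes

The test suite and the acceptance script run the heavier experiments at the
sizes the defaults define: 900 counties for coefficient recovery and the
full pipeline, 400 for the model-selection comparison, 50×50 niche grids.
These sizes are the package's chosen study conditions; results at larger
lattices differ only in sampling noise.

## Known limitations

* Peak tracking is greedy nearest-neighbour; peaks that merge or split
  between censuses produce lineage churn rather than explicit merge events.
* The IDW neighbourhood is global; for very large station sets a cutoff or
  KD-tree truncation would be needed for speed, but correctness-first was
  chosen at desk scale.
* The GWR fallback schedule widens bandwidths per *location*; mixing
  fractions within one fit slightly blurs the interpretation of enp, so
  fallbacks are logged and the fractions used are recorded per location.
* File mode expects the documented CSV headers; no schema inference is
  attempted.
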