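# climniche

Tools for quantifying how a human population redistributes itself across
climate space, built around county-level census data: demographic growth
rates and their climatic and socio-economic predictors, population-weighted
climate *exposure* versus the area-averaged climate, the realized
climate-niche surface and its peaks, and a from-scratch geographically
weighted regression (GWR) for ranking correlates of growth under spatial
non-stationarity.

It is aimed at biostatisticians and spatial demographers who want the whole
chain — from raw county tables and monthly climate series to AICc model
comparisons — as tested, scriptable building blocks rather than a GIS
workflow.

## The quantities at the core

**Growth rate.** For county density `hd` over a census interval
`(t0, t1)`,

    lambda = ln(hd(t1) / hd(t0)) / (t1 - t0)

a per-year rate that is independent of the density level (a geometric
variant `(hd1/hd0)^(1/dt) - 1` is a config switch).

**Climate normals.** From monthly series, per year: annual mean
temperature, SD of the 12 monthly temperatures (temperature seasonality),
annual precipitation total and SD of monthly totals; averaged over 20-year
horizons and interpolated to county centroids by inverse distance
weighting.

**Exposure vs. climate change.** For a climate variable `c` with county
populations `p_i`,

    exposure = sum_i p_i c_i / sum_i p_i        (the average citizen)
    area mean = mean_i c_i                      (the average county)

When growth concentrates in particular climates, exposure can move several
times faster than the area mean; the ratio of the two endpoint changes is
the *demographic amplification* of climate change.

**Niche surface.** Population binned over a 2-D climate grid (annual
temperature x temperature seasonality by default), `log10(1 + pop)`
smoothed by local quadratic LOESS (tricube weights, nearest `ceil(alpha*N)`
cells, `alpha = 0.3`), with strict interior local maxima reported as niche
peaks and tracked across censuses.

**GWR.** One weighted least-squares regression per county,
`beta_i = (X'W_iX)^-1 X'W_i y`, with bi-square weights
`w = (1 - (d/b)^2)^2` and an adaptive bandwidth `b_i` equal to the distance
to the `ceil(f*(n-1))`-th nearest county (default `f = 0.3`).  Models are
compared by the GWR small-sample AICc with the trace of the hat matrix as
effective parameters, and summarized by Akaike weights and the share of
counties where each standardized coefficient is largest in absolute value.

A seeded synthetic-data generator reproduces the structure of the inputs —
lattice counties, seasonal climate fields with optional drift, skewed
covariates, censuses advanced under known coefficient surfaces — so every
stage has ground truth to test against.

## Worked example

```sh
climniche run-all --n-side 10 --seed 3 --outdir out
climniche summarize out
```

```
exposure vs area-mean change, 1920 -> 2000:
  annual_temp: exposure +1.515, area +0.240 (amplification 6.31x)
  temp_seasonality: exposure -0.063, area +0.000 (amplification undefined)
  ...
GWR model comparison (Akaike weights):
  1900-1920: best OLS_C+NC (w=1.0000, enp=9.0)
  ...
relative importance (climatic-group share, top predictor):
  1900-1920: climatic share 0.340, top waterway_sqrt (0.620)
```

Reading it: over the simulated century the area-averaged temperature rose
0.24 °C (the configured 0.003 °C/yr drift over 80 years), but because
population growth concentrated in warm counties, the temperature
experienced by the average citizen rose 1.515 °C — 6.31 times faster.  On
this small 100-county lattice the spatial coefficient variation is too weak
for GWR to beat global OLS (Akaike weight 1 for `OLS_C+NC`), and the
square-root waterway distance is the strongest single correlate of growth
in most counties.  At the full 900-county default the non-stationary
`GWR_C+NC` model dominates instead.

The same stages are available individually (`simulate`, `normals`,
`growth`, `exposure`, `niche`, `gwr`) and as library functions
(`climniche.fit_gwr`, `climniche.exposure_trajectory`, ...), reading and
writing plain CSV.

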