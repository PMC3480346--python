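"""Seeded synthetic county datasets with known ground truth.

The generator emulates the shape of the real inputs — a set of counties with
census populations every 20 years, skewed socio-economic covariates, and
gridded monthly climate series — on a planar lattice where everything is
known exactly:

* counties sit on an ``n_side x n_side`` unit-spaced grid, land area 1;
* monthly temperature is an affine spatial field plus a sinusoidal seasonal
  cycle and an optional linear secular trend (precipitation analogous,
  floored at 0);
* census populations are advanced from seeded log-normal initial densities
  with growth rates lambda = sum_j beta_j(u, v) * x_j + eps, where the
  beta_j(u, v) coefficient surfaces (constant, linear gradient, or Gaussian
  bump) are recorded as ground truth, eps ~ N(0, noise_sd), and the density
  update uses the same growth-rate form as the analysis (exact round trips);
* income is log-normal (right-skewed), agricultural fraction lies in [0, 1],
  and waterway distance is the distance to the western lattice edge.

Scenario builders at the bottom assemble purpose-built bundles: an
*amplification* scenario where climate is constant but warm counties grow
faster (with the analytic exposure trajectory attached), a *gradient*
scenario with linearly varying coefficient surfaces for parameter-recovery
checks, and a *model-selection* scenario with spatially varying climate
effects and constant non-climate effects.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import demography
from .exceptions import ConfigurationError, GenerationError

logger = logging.getLogger(__name__)

DEFAULT_CENSUS_YEARS = (1900, 1920, 1940, 1960, 1980, 2000)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ClimateSpec:
    """Spatial gradients, seasonal amplitude and drift of the climate fields.

    Units: temperature degC, precipitation mm/month, coordinates in lattice
    units.  ``*_micro_sd`` add a seeded, time-constant per-station offset to
    the base field and amplitude (default 0, i.e. the fields are exactly the
    stated closed forms); amplitude gradients let seasonality vary in space.
    """
    temp_base: float = 12.0
    temp_gx: float = -0.15
    temp_gy: float = -0.6
    temp_amplitude: float = 8.0
    temp_amp_gx: float = 0.0
    temp_amp_gy: float = 0.0
    temp_micro_sd: float = 0.0
    precip_base: float = 80.0
    precip_gx: float = 1.0
    precip_gy: float = 0.5
    precip_amplitude: float = 30.0
    precip_amp_gx: float = 0.0
    precip_amp_gy: float = 0.0
    precip_micro_sd: float = 0.0
    precip_trend_per_year: float = 0.0


def _default_surfaces() -> Dict[str, dict]:
    # per-year growth-rate contributions of z-scored predictors; magnitudes
    # chosen so county lambda varies on the ~0.01/yr scale of census data
    return {
        "annual_temp": {"kind": "linear", "base": 0.008,
                        "gx": -0.0003, "gy": 0.0},
        "temp_seasonality": {"kind": "gaussian", "base": -0.004,
                             "amplitude": -0.006, "x0": 20.0, "y0": 8.0,
                             "width": 8.0},
        "annual_precip": {"kind": "constant", "value": 0.003},
        "precip_seasonality": {"kind": "constant", "value": -0.002},
        "log_density": {"kind": "linear", "base": 0.002,
                        "gx": 0.0, "gy": 0.00015},
        "income_z": {"kind": "constant", "value": 0.004},
        "ag_density": {"kind": "constant", "value": -0.003},
        "waterway_sqrt": {"kind": "constant", "value": -0.002},
    }


@dataclass
class SyntheticConfig:
    """Everything the generator needs; fully determines the dataset with
    ``seed``."""
    n_side: int = 30
    census_years: Tuple[int, ...] = DEFAULT_CENSUS_YEARS
    seed: int = 0
    noise_sd: float = 0.01
    coefficient_surfaces: Dict[str, dict] = field(
        default_factory=_default_surfaces)
    # default study conditions carry station-level microclimate texture and
    # spatially varying seasonal amplitude: interpolated real climate is never
    # exactly affine, and with a purely affine field the four climate
    # variables would be collinear inside every kernel neighbourhood
    climate: ClimateSpec = field(default_factory=lambda: ClimateSpec(
        temp_micro_sd=1.0, precip_micro_sd=6.0,
        temp_amp_gx=0.04, temp_amp_gy=0.02,
        precip_amp_gx=-0.15, precip_amp_gy=0.25))
    trend_per_year: float = 0.003        # temperature drift, degC/yr
    growth_form: str = "log"
    initial_density_log10_mean: float = 1.6   # median ~40 people / unit^2
    initial_density_log10_sd: float = 0.5
    station_offset: Tuple[float, float] = (0.0, 0.0)
    income_year_jitter_sd: float = 0.1

    def __post_init__(self):
        if self.n_side < 3:
            raise ConfigurationError("n_side must be >= 3")
        years = tuple(self.census_years)
        if len(years) < 2 or any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigurationError("census_years must be strictly increasing")
        steps = {b - a for a, b in zip(years, years[1:])}
        if len(steps) != 1:
            raise ConfigurationError("census_years must be equally spaced")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.growth_form not in demography.GROWTH_FORMS:
            raise ConfigurationError(f"unknown growth form {self.growth_form!r}")
        self.census_years = years

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "climate" in d and isinstance(d["climate"], Mapping):
            d["climate"] = ClimateSpec(**d["climate"])
        for key in ("census_years", "station_offset"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def evaluate_surface(spec: Mapping, x, y):
    """Evaluate a coefficient-surface spec at lattice coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kind = spec.get("kind")
    if kind == "constant":
        return np.full_like(x, float(spec["value"]))
    if kind == "linear":
        return (float(spec.get("base", 0.0))
                + float(spec.get("gx", 0.0)) * x
                + float(spec.get("gy", 0.0)) * y)
    if kind == "gaussian":
        w = float(spec["width"])
        if w <= 0:
            raise ConfigurationError("gaussian surface width must be positive")
        r2 = (x - float(spec["x0"])) ** 2 + (y - float(spec["y0"])) ** 2
        return (float(spec.get("base", 0.0))
                + float(spec["amplitude"]) * np.exp(-r2 / (2 * w * w)))
    raise ConfigurationError(f"unknown surface kind {kind!r}")


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """What the generator knows and the analysis tries to recover."""
    true_beta: pd.DataFrame          # county x predictor
    true_lambda_mean: pd.DataFrame   # county x interval-start (noiseless)
    scenario_tag: str = "default"


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_county_lattice(config: SyntheticConfig) -> pd.DataFrame:
    """n_side^2 counties on a unit-spaced planar grid, land area 1."""
    s = config.n_side
    xs, ys = np.meshgrid(np.arange(s, dtype=float),
                         np.arange(s, dtype=float), indexing="ij")
    ids = [f"c{i:04d}" for i in range(s * s)]
    return pd.DataFrame({"county_id": ids, "x": xs.ravel(), "y": ys.ravel(),
                         "land_area": 1.0})


def generate_monthly_climate(config: SyntheticConfig,
                             years: Sequence[int]) -> pd.DataFrame:
    """Monthly station series over a year range.

    temperature = base + gx*x + gy*y + A(x,y)*sin(2*pi*month/12)
                  + trend_per_year * (year - start)  [+ station micro offset]

    with the precipitation analogue floored at 0.  Stations sit at county
    centroids plus ``station_offset``.
    """
    years = list(years)
    if not years:
        raise ConfigurationError("year range must be nonempty")
    y0 = min(years)
    cs = config.climate
    counties = generate_county_lattice(config)
    ox, oy = config.station_offset
    sx = counties["x"].to_numpy() + ox
    sy = counties["y"].to_numpy() + oy
    n = len(counties)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    t_micro = rng.normal(0.0, cs.temp_micro_sd, n) if cs.temp_micro_sd else np.zeros(n)
    p_micro = rng.normal(0.0, cs.precip_micro_sd, n) if cs.precip_micro_sd else np.zeros(n)

    t_base = cs.temp_base + cs.temp_gx * sx + cs.temp_gy * sy + t_micro
    t_amp = np.maximum(0.0, cs.temp_amplitude + cs.temp_amp_gx * sx
                       + cs.temp_amp_gy * sy)
    p_base = cs.precip_base + cs.precip_gx * sx + cs.precip_gy * sy + p_micro
    p_amp = np.maximum(0.0, cs.precip_amplitude + cs.precip_amp_gx * sx
                       + cs.precip_amp_gy * sy)

    months = np.arange(1, 13)
    season = np.sin(2 * np.pi * months / 12.0)
    frames = []
    sid = [f"s{i:04d}" for i in range(n)]
    for year in years:
        t_drift = config.trend_per_year * (year - y0)
        p_drift = cs.precip_trend_per_year * (year - y0)
        temp = t_base[:, None] + t_drift + t_amp[:, None] * season[None, :]
        precip = np.maximum(0.0, p_base[:, None] + p_drift
                            + p_amp[:, None] * season[None, :])
        frames.append(pd.DataFrame({
            "station_id": np.repeat(sid, 12),
            "x": np.repeat(sx, 12),
            "y": np.repeat(sy, 12),
            "year": year,
            "month": np.tile(months, n),
            "temp": temp.ravel(),
            "precip": precip.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def generate_covariates(counties: pd.DataFrame,
                        config: SyntheticConfig) -> pd.DataFrame:
    """Income (log-normal, per census year), agricultural fraction in [0, 1],
    and distance to the western lattice edge (the designated waterway)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = len(counties)
    out = pd.DataFrame({"county_id": counties["county_id"].to_numpy()})
    county_effect = rng.normal(0.0, 0.4, n)
    for y in config.census_years:
        jitter = (rng.normal(0.0, config.income_year_jitter_sd, n)
                  if config.income_year_jitter_sd else 0.0)
        out[f"income_{y}"] = np.exp(math.log(30_000.0) + county_effect + jitter)
    ag_frac = np.clip(rng.beta(2.0, 3.0, n), 0.0, 1.0)
    land = counties["land_area"].to_numpy()
    for y in config.census_years:
        out[f"ag_{y}"] = ag_frac * land      # static extent; fraction in [0,1]
    out["waterway_dist"] = counties["x"].to_numpy()
    return out


def generate_population_history(counties: pd.DataFrame,
                                predictors: Union[pd.DataFrame,
                                                  Mapping[int, pd.DataFrame]],
                                config: SyntheticConfig,
                                standardize: bool = True
                                ) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Advance census populations with known coefficient surfaces.

    ``predictors``: a county-indexed DataFrame of predictor values (used for
    every interval) or a mapping interval-start-year -> DataFrame.  Columns
    must match the keys of ``config.coefficient_surfaces``; by default each
    column is z-scored before the coefficients are applied, so the recorded
    ``true_beta`` is on the standardized-predictor scale the analysis fits.

    Returns a wide population table (``county_id, pop_<year>...``) and the
    :class:`SyntheticTruth` with per-county beta surfaces and noiseless
    lambda per interval.
    """
    years = list(config.census_years)
    n = len(counties)
    names = list(config.coefficient_surfaces)
    x = counties["x"].to_numpy(dtype=float)
    y = counties["y"].to_numpy(dtype=float)
    beta = np.column_stack([
        evaluate_surface(config.coefficient_surfaces[name], x, y)
        for name in names]) if names else np.zeros((n, 0))

    def design_for(t0: int) -> np.ndarray:
        frame = predictors[t0] if isinstance(predictors, Mapping) else predictors
        missing = [c for c in names if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"predictor frame lacks columns {missing}")
        M = frame[names].to_numpy(dtype=float) if names else np.zeros((n, 0))
        if standardize and names:
            sd = M.std(axis=0, ddof=1)
            ok = sd > 0
            if not ok.all():
                logger.warning("constant predictor column(s) %s left at 0",
                               [names[j] for j in np.flatnonzero(~ok)])
            M = np.where(ok, (M - M.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
        return M

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    hd = 10.0 ** rng.normal(config.initial_density_log10_mean,
                            config.initial_density_log10_sd, n)
    land = counties["land_area"].to_numpy(dtype=float)
    pops = {years[0]: hd * land}
    lam_mean = np.empty((n, len(years) - 1))
    for k, (t0, t1) in enumerate(zip(years[:-1], years[1:])):
        M = design_for(t0)
        lam0 = (M * beta).sum(axis=1)
        eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else 0.0
        lam = lam0 + eps
        try:
            hd = demography.advance_density(hd, lam, t0, t1,
                                            form=config.growth_form)
        except Exception as exc:
            raise GenerationError(
                f"cannot advance populations over {t0}-{t1}: {exc}") from exc
        if np.any(hd <= 0) or not np.all(np.isfinite(hd)):
            raise GenerationError(
                f"population underflow/overflow in interval {t0}-{t1}; "
                "shrink noise_sd or the coefficient surfaces")
        pops[t1] = hd * land
        lam_mean[:, k] = lam0

    pop_table = pd.DataFrame({"county_id": counties["county_id"].to_numpy(),
                              **{f"pop_{yv}": pops[yv] for yv in years}})
    truth = SyntheticTruth(
        true_beta=pd.DataFrame(beta, columns=names,
                               index=counties["county_id"].to_numpy()),
        true_lambda_mean=pd.DataFrame(
            lam_mean, columns=[t0 for t0 in years[:-1]],
            index=counties["county_id"].to_numpy()),
    )
    return pop_table, truth


def assemble_county_table(counties: pd.DataFrame,
                          covariates: pd.DataFrame,
                          populations: pd.DataFrame) -> pd.DataFrame:
    """Merge lattice, covariates and populations into the wide county CSV
    layout the demography module reads."""
    out = counties.merge(covariates, on="county_id")
    return out.merge(populations, on="county_id")


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """A ready-to-analyse synthetic dataset plus whatever is analytically
    known about it."""
    config: SyntheticConfig
    counties: pd.DataFrame
    county_table: pd.DataFrame
    truth: Optional[SyntheticTruth] = None
    normals: Optional[pd.DataFrame] = None
    monthly: Optional[pd.DataFrame] = None
    expected_exposure: Optional[pd.DataFrame] = None
    scenario_tag: str = "default"


def make_amplification_scenario(config: Optional[SyntheticConfig] = None,
                                sensitivity: float = 0.002,
                                initial_population: float = 1000.0
                                ) -> DatasetBundle:
    """Constant climate, growth strictly increasing in county temperature.

    lambda_i = sensitivity * T_i per year, so population concentrates in warm
    counties while the area-mean climate never moves.  The bundle carries the
    analytic exposure trajectory E(t) = sum_i T_i p_i(t) / sum_i p_i(t)
    computed from the generating rule (not through the analysis code), for
    use as an oracle.
    """
    if config is None:
        config = SyntheticConfig(trend_per_year=0.0, noise_sd=0.0)
    if config.trend_per_year != 0 or config.climate.precip_trend_per_year != 0:
        raise ConfigurationError("amplification scenario requires zero "
                                 "climate trend")
    years = list(config.census_years)
    counties = generate_county_lattice(config)
    monthly = generate_monthly_climate(config, range(years[1] - 19,
                                                     years[-1] + 1))
    from .climate import compute_normals
    normals = compute_normals(monthly, counties, years)
    h0, h1 = years[1] - 19, years[1]
    T = (normals[(normals["horizon_start"] == h0)
                 & (normals["horizon_end"] == h1)]
         .set_index("county_id")["annual_temp"]
         .reindex(counties["county_id"]).to_numpy())

    pops = {years[0]: np.full(len(counties), float(initial_population))}
    lam = sensitivity * T
    for t0, t1 in zip(years[:-1], years[1:]):
        pops[t1] = demography.advance_density(pops[t0], lam, t0, t1,
                                              form=config.growth_form)
    county_table = pd.DataFrame({
        "county_id": counties["county_id"].to_numpy(),
        **{f"pop_{yv}": pops[yv] for yv in years}})
    expected = pd.DataFrame({
        "year": years,
        "expected_exposure": [float(np.dot(T, pops[yv]) / pops[yv].sum())
                              for yv in years],
        "expected_area_mean": float(T.mean()),
    })
    county_table = counties.merge(county_table, on="county_id")
    truth = SyntheticTruth(
        true_beta=pd.DataFrame({"annual_temp": np.full(len(counties),
                                                       sensitivity)},
                               index=counties["county_id"].to_numpy()),
        true_lambda_mean=pd.DataFrame(
            np.tile(lam[:, None], (1, len(years) - 1)),
            columns=years[:-1], index=counties["county_id"].to_numpy()),
        scenario_tag="amplification")
    return DatasetBundle(config=config, counties=counties,
                         county_table=county_table, truth=truth,
                         normals=normals, monthly=monthly,
                         expected_exposure=expected,
                         scenario_tag="amplification")


def make_gradient_scenario(n_side: int = 30, noise_sd: float = 0.05,
                           seed: int = 0, n_predictors: int = 3
                           ) -> DatasetBundle:
    """Linear-gradient coefficient surfaces over iid standard-normal
    predictors; the workhorse for parameter-recovery checks."""
    s = n_side
    surfaces = {}
    # unit-norm gradient directions with a common span so every coefficient
    # surface has the same spatial SD (each predictor equally recoverable)
    rt = math.sqrt(0.5)
    specs = [(0.05, 0.10, 1.0, 0.0), (-0.02, 0.10, 0.0, 1.0),
             (0.03, 0.10, rt, rt), (0.01, 0.10, -rt, rt)]
    for j in range(n_predictors):
        base, span, ux, uy = specs[j % len(specs)]
        surfaces[f"p{j + 1}"] = {
            "kind": "linear",
            "base": base - 0.5 * span * (ux + uy),
            "gx": span * ux / (s - 1),
            "gy": span * uy / (s - 1)}
    config = SyntheticConfig(n_side=s, seed=seed, noise_sd=noise_sd,
                             coefficient_surfaces=surfaces)
    counties = generate_county_lattice(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    predictors = pd.DataFrame(
        rng.standard_normal((len(counties), n_predictors)),
        columns=[f"p{j + 1}" for j in range(n_predictors)])
    pop_table, truth = generate_population_history(counties, predictors,
                                                   config)
    truth.scenario_tag = "gradient"
    county_table = counties.merge(pop_table, on="county_id")
    # keep the (standardized) predictors alongside for direct GWR fitting
    M = predictors.to_numpy()
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    for j, c in enumerate(predictors.columns):
        county_table[c] = M[:, j]
    return DatasetBundle(config=config, counties=counties,
                         county_table=county_table, truth=truth,
                         scenario_tag="gradient")


def make_model_selection_scenario(n_side: int = 20, noise_sd: float = 0.01,
                                  seed: int = 0) -> DatasetBundle:
    """Spatially varying climate effects, constant non-climate effects.

    Climate fields get per-station microclimate jitter and amplitude
    gradients so the four derived climate variables are locally independent
    (a purely affine field would make every bisquare neighbourhood rank
    deficient); incomes are held fixed across censuses so the generating
    model matches the fitted one.
    """
    s = n_side
    surfaces = {
        "annual_temp": {"kind": "linear", "base": -0.01,
                        "gx": 0.04 / (s - 1), "gy": 0.0},
        "temp_seasonality": {"kind": "linear", "base": 0.015,
                             "gx": 0.0, "gy": -0.03 / (s - 1)},
        "annual_precip": {"kind": "gaussian", "base": 0.0, "amplitude": 0.02,
                          "x0": 0.3 * (s - 1), "y0": 0.7 * (s - 1),
                          "width": 0.3 * (s - 1)},
        "precip_seasonality": {"kind": "linear", "base": -0.012,
                               "gx": 0.024 / (s - 1), "gy": 0.0},
        "income_z": {"kind": "constant", "value": 0.004},
        "ag_density": {"kind": "constant", "value": -0.003},
        "waterway_sqrt": {"kind": "constant", "value": -0.002},
    }
    climate = ClimateSpec(temp_micro_sd=1.5, precip_micro_sd=8.0,
                          temp_amp_gx=0.05, temp_amp_gy=0.02,
                          precip_amp_gx=-0.2, precip_amp_gy=0.35)
    config = SyntheticConfig(n_side=s, seed=seed, noise_sd=noise_sd,
                             coefficient_surfaces=surfaces, climate=climate,
                             trend_per_year=0.003,
                             income_year_jitter_sd=0.0)
    counties = generate_county_lattice(config)
    years = list(config.census_years)
    monthly = generate_monthly_climate(config, range(years[1] - 19,
                                                     years[-1] + 1))
    from .climate import compute_normals
    normals = compute_normals(monthly, counties, years)
    covariates = generate_covariates(counties, config)

    # predictor frame on the generator's side: first-horizon climate plus the
    # transformed static covariates
    h0, h1 = years[1] - 19, years[1]
    clim = (normals[(normals["horizon_start"] == h0)
                    & (normals["horizon_end"] == h1)]
            .set_index("county_id")
            .reindex(counties["county_id"]))
    frame = pd.DataFrame(index=counties.index)
    for v in ("annual_temp", "temp_seasonality", "annual_precip",
              "precip_seasonality"):
        frame[v] = clim[v].to_numpy()
    frame["income_z"] = demography.zscore(
        covariates[f"income_{years[0]}"].to_numpy())
    frame["ag_density"] = demography.agricultural_density(
        covariates[f"ag_{years[0]}"].to_numpy(),
        counties["land_area"].to_numpy())
    frame["waterway_sqrt"] = demography.waterway_sqrt(
        covariates["waterway_dist"].to_numpy())

    pop_table, truth = generate_population_history(counties, frame, config)
    truth.scenario_tag = "model_selection"
    county_table = assemble_county_table(counties, covariates, pop_table)
    return DatasetBundle(config=config, counties=counties,
                         county_table=county_table, truth=truth,
                         normals=normals, monthly=monthly,
                         scenario_tag="model_selection")


def make_default_dataset(config: Optional[SyntheticConfig] = None
                         ) -> DatasetBundle:
    """The full default study conditions: lattice counties, drifting climate,
    covariates, and populations driven by the default coefficient surfaces
    (climate predictors taken from the first-horizon normals)."""
    if config is None:
        config = SyntheticConfig()
    counties = generate_county_lattice(config)
    years = list(config.census_years)
    monthly = generate_monthly_climate(config, range(years[1] - 19,
                                                     years[-1] + 1))
    from .climate import compute_normals
    normals = compute_normals(monthly, counties, years)
    covariates = generate_covariates(counties, config)

    names = list(config.coefficient_surfaces)
    h0, h1 = years[1] - 19, years[1]
    clim = (normals[(normals["horizon_start"] == h0)
                    & (normals["horizon_end"] == h1)]
            .set_index("county_id").reindex(counties["county_id"]))
    frame = pd.DataFrame(index=counties.index)
    for v in names:
        if v in clim.columns:
            frame[v] = clim[v].to_numpy()
    if "income_z" in names:
        frame["income_z"] = demography.zscore(
            covariates[f"income_{years[0]}"].to_numpy())
    if "ag_density" in names:
        frame["ag_density"] = demography.agricultural_density(
            covariates[f"ag_{years[0]}"].to_numpy(),
            counties["land_area"].to_numpy())
    if "waterway_sqrt" in names:
        frame["waterway_sqrt"] = demography.waterway_sqrt(
            covariates["waterway_dist"].to_numpy())
    if "log_density" in names:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
        hd0 = 10.0 ** rng.normal(config.initial_density_log10_mean,
                                 config.initial_density_log10_sd,
                                 len(counties))
        frame["log_density"] = np.log10(hd0)

    pop_table, truth = generate_population_history(counties, frame, config)
    county_table = assemble_county_table(counties, covariates, pop_table)
    return DatasetBundle(config=config, counties=counties,
                         county_table=county_table, truth=truth,
                         normals=normals, monthly=monthly,
                         scenario_tag="default")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bundle(bundle: DatasetBundle, outdir) -> Dict[str, str]:
    """Write the bundle's tables as CSV (config as YAML); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    bundle.config.to_yaml(outdir / "config.yaml")
    paths["config"] = str(outdir / "config.yaml")
    bundle.county_table.to_csv(outdir / "county_table.csv", index=False)
    paths["county_table"] = str(outdir / "county_table.csv")
    if bundle.monthly is not None:
        bundle.monthly.to_csv(outdir / "monthly_climate.csv", index=False)
        paths["monthly_climate"] = str(outdir / "monthly_climate.csv")
    if bundle.normals is not None:
        bundle.normals.to_csv(outdir / "climate_normals.csv", index=False)
        paths["climate_normals"] = str(outdir / "climate_normals.csv")
    if bundle.truth is not None:
        bundle.truth.true_beta.to_csv(outdir / "true_beta.csv",
                                      index_label="county_id")
        bundle.truth.true_lambda_mean.to_csv(outdir / "true_lambda.csv",
                                             index_label="county_id")
        paths["true_beta"] = str(outdir / "true_beta.csv")
        paths["true_lambda"] = str(outdir / "true_lambda.csv")
    if bundle.expected_exposure is not None:
        bundle.expected_exposure.to_csv(outdir / "expected_exposure.csv",
                                        index=False)
        paths["expected_exposure"] = str(outdir / "expected_exposure.csv")
    return paths
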