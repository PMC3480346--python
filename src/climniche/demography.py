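"""County demography: densities, annual growth rates, and predictor transforms.

The response variable of the whole analysis is the per-county *human density
annual growth rate* over a 20-year census interval,

    lambda = ln(hd(t1) / hd(t0)) / (t1 - t0)        (continuous form, default)

which is independent of the absolute density level: doubling both densities
leaves lambda unchanged.  A discrete (geometric) alternative
``(hd1/hd0)**(1/(t1-t0)) - 1`` is available via ``form="geometric"``; both are
density-independent and the choice only rescales lambda slightly for the
growth magnitudes seen in census data.

The module also implements the non-climate predictor transforms used
downstream: log10 density, within-census income z-scores (with weighted
interpolation for censuses lacking an income question), arc-sine-square-root
agricultural density, and square-root waterway distance.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateInputError,
    DomainError,
    PipelineError,
)

logger = logging.getLogger(__name__)

#: canonical predictor order used everywhere downstream (ties in relative
#: importance are broken by this order)
CLIMATIC_PREDICTORS = (
    "annual_temp",
    "temp_seasonality",
    "annual_precip",
    "precip_seasonality",
)
NONCLIMATIC_PREDICTORS = (
    "log_density",
    "income_z",
    "ag_density",
    "waterway_sqrt",
)
ALL_PREDICTORS = CLIMATIC_PREDICTORS + NONCLIMATIC_PREDICTORS

GROWTH_FORMS = ("log", "geometric")


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def population_density(population, land_area):
    """People per unit area.  ``land_area`` must be positive."""
    population = np.asarray(population, dtype=float)
    land_area = np.asarray(land_area, dtype=float)
    if np.any(land_area <= 0):
        raise DomainError("land_area must be positive")
    if np.any(population < 0):
        raise DomainError("population must be nonnegative")
    out = population / land_area
    return float(out) if out.ndim == 0 else out


def growth_rate(hd0, hd1, t0, t1, form: str = "log"):
    """Annual growth rate of density between two censuses.

    Parameters
    ----------
    hd0, hd1
        Positive densities at the start and end of the interval.  Arrays are
        broadcast elementwise.
    t0, t1
        Census years, ``t1 > t0``.
    form
        ``"log"`` (default): ``ln(hd1/hd0) / (t1 - t0)``.
        ``"geometric"``: ``(hd1/hd0)**(1/(t1-t0)) - 1``.
    """
    if form not in GROWTH_FORMS:
        raise ConfigurationError(f"unknown growth form {form!r}")
    if t1 <= t0:
        raise DomainError(f"t1={t1} must exceed t0={t0}")
    hd0 = np.asarray(hd0, dtype=float)
    hd1 = np.asarray(hd1, dtype=float)
    if np.any(hd0 <= 0) or np.any(hd1 <= 0):
        raise DomainError("densities must be positive")
    dt = float(t1 - t0)
    ratio = hd1 / hd0
    if form == "log":
        out = np.log(ratio) / dt
    else:
        out = ratio ** (1.0 / dt) - 1.0
    return float(out) if out.ndim == 0 else out


def advance_density(hd0, lam, t0, t1, form: str = "log"):
    """Inverse of :func:`growth_rate`: density after growing at rate ``lam``.

    Single source of truth for the synthetic generator, so round-tripping
    generated populations through :func:`growth_rate` is exact by construction.
    """
    if form not in GROWTH_FORMS:
        raise ConfigurationError(f"unknown growth form {form!r}")
    if t1 <= t0:
        raise DomainError(f"t1={t1} must exceed t0={t0}")
    hd0 = np.asarray(hd0, dtype=float)
    lam = np.asarray(lam, dtype=float)
    dt = float(t1 - t0)
    if form == "log":
        out = hd0 * np.exp(lam * dt)
    else:
        if np.any(1.0 + lam <= 0):
            raise DomainError("geometric growth undefined for rates <= -1")
        out = hd0 * (1.0 + lam) ** dt
    return float(out) if out.ndim == 0 else out


def log_density(hd):
    """Base-10 log of density; densities must be strictly positive."""
    hd = np.asarray(hd, dtype=float)
    if np.any(hd <= 0):
        raise DomainError("density must be positive for log transform")
    out = np.log10(hd)
    return float(out) if out.ndim == 0 else out


def zscore(values) -> np.ndarray:
    """Z-scores with sample SD (denominator n-1).

    Raises :class:`DegenerateInputError` when the SD is zero (constant input)
    or fewer than two values are supplied.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise DomainError("zscore expects a 1-D vector")
    if v.size < 2:
        raise DegenerateInputError("zscore needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zscore undefined for zero-variance input")
    return (v - v.mean()) / sd


def interpolate_income(z_a: float, z_b: float, w_a: float, w_b: float) -> float:
    """Weighted average of two income z-scores (used for censuses with no
    usable income question, e.g. weights 0.333/0.667 interpolating 1960 from
    the 1940 and 1970 censuses)."""
    if abs(w_a + w_b - 1.0) > 1e-9:
        raise ConfigurationError(f"weights must sum to 1, got {w_a + w_b}")
    return w_a * z_a + w_b * z_b


def categorical_income_mean(counts: Sequence[float],
                            bounds: Sequence[tuple]) -> float:
    """Mean income from a banded frequency table: people-weighted average of
    category midpoints (how categorical census income is collapsed to one
    number per county)."""
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(bounds):
        raise DomainError("counts and bounds must align")
    if np.any(counts < 0):
        raise DomainError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise DomainError("at least one category count must be positive")
    mids = []
    for lo, hi in bounds:
        if not lo < hi:
            raise DomainError(f"category bounds must satisfy low < high, got ({lo}, {hi})")
        mids.append(0.5 * (lo + hi))
    return float(np.dot(counts, mids) / total)


def agricultural_density(ag_extent, land_area):
    """Arc-sine square-root transform of the crop+pasture fraction of county
    area; range [0, pi/2] radians.  Fractions above 1 (extent slightly larger
    than the land area due to source mismatches) are clipped to 1."""
    ag_extent = np.asarray(ag_extent, dtype=float)
    land_area = np.asarray(land_area, dtype=float)
    if np.any(land_area <= 0):
        raise DomainError("land_area must be positive")
    if np.any(ag_extent < 0):
        raise DomainError("agricultural extent must be nonnegative")
    frac = np.minimum(1.0, ag_extent / land_area)
    out = np.arcsin(np.sqrt(frac))
    return float(out) if out.ndim == 0 else out


def waterway_sqrt(d):
    """Square-root transform of distance to the nearest navigable waterway."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("distance must be nonnegative")
    out = np.sqrt(d)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

def filter_complete_counties(counties: pd.DataFrame,
                             census_years: Iterable[int]) -> pd.DataFrame:
    """Keep only counties with a population figure at every census year.

    Mirrors restricting a century-long analysis to counties with consistent
    records throughout; input row order is preserved.
    """
    years = list(census_years)
    cols = [f"pop_{y}" for y in years]
    missing_cols = [c for c in cols if c not in counties.columns]
    if missing_cols:
        raise DataError(f"county table lacks columns: {missing_cols}")
    mask = counties[cols].notna().all(axis=1)
    out = counties.loc[mask].copy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("filter_complete_counties: dropped %d of %d counties",
                    n_dropped, len(counties))
    if out.empty:
        raise PipelineError("no county has complete census coverage")
    return out


def income_zscores(counties: pd.DataFrame,
                   census_years: Sequence[int]) -> pd.DataFrame:
    """Within-census income z-scores, interpolating censuses with no data.

    For each year with an ``income_<year>`` column the raw values are z-scored
    across counties (sample SD).  A year whose column is entirely absent or
    all-missing is filled by time-weighted interpolation between the nearest
    bracketing censuses that do have data (weights proportional to temporal
    proximity).  Counties missing income in a year with data are interpolated
    the same way when both neighbours exist, otherwise left NaN (and later
    excluded from that interval with a warning).
    """
    years = list(census_years)
    z = pd.DataFrame(index=counties.index, columns=years, dtype=float)
    have = []
    for y in years:
        col = f"income_{y}"
        if col in counties.columns and counties[col].notna().any():
            vals = counties[col].astype(float)
            ok = vals.notna()
            z.loc[ok, y] = zscore(vals[ok].to_numpy())
            have.append(y)
    if not have:
        raise DataError("no census year has income data")
    for y in years:
        needs = z[y].isna()
        if not needs.any():
            continue
        before = [h for h in have if h < y]
        after = [h for h in have if h > y]
        if before and after:
            a, b = before[-1], after[0]
            w_b = (y - a) / (b - a)
            w_a = 1.0 - w_b
            fill = w_a * z[a] + w_b * z[b]
            z.loc[needs, y] = fill[needs]
            logger.info("income_zscores: interpolated %d counties for %d "
                        "from %d (w=%.3f) and %d (w=%.3f)",
                        int(needs.sum()), y, a, w_a, b, w_b)
        else:
            logger.warning("income_zscores: year %d not interpolable "
                           "(%d counties left missing)", y, int(needs.sum()))
    return z


def build_growth_table(counties: pd.DataFrame,
                       normals: pd.DataFrame,
                       census_years: Sequence[int],
                       form: str = "log") -> pd.DataFrame:
    """Assemble the long table of growth rates and the 8 predictors.

    Parameters
    ----------
    counties
        Wide county table with columns ``county_id, x, y, land_area,
        pop_<year>..., income_<year>..., ag_<year>..., waterway_dist``.
        Only counties complete at every census year are used.
    normals
        Climate normals keyed by ``county_id, horizon_start, horizon_end``
        with the four climate variables (see :mod:`climniche.climate`).
    census_years
        Ordered census years; consecutive pairs define the intervals.
    form
        Growth-rate form, passed to :func:`growth_rate`.

    Returns
    -------
    DataFrame with one row per county x interval: ``county_id, x, y, t0, t1,
    lambda`` plus the 8 predictor columns.  Climate predictors come from the
    20-year horizon ending at ``t1``; non-climate predictors are measured at
    ``t0``.  Rows with any missing predictor are dropped with a warning.
    """
    from .climate import assign_horizon  # local import to avoid cycle

    years = list(census_years)
    counties = filter_complete_counties(counties, years)
    income_z = income_zscores(counties, years)

    rows = []
    for t0, t1 in zip(years[:-1], years[1:]):
        hd0 = population_density(counties[f"pop_{t0}"].to_numpy(),
                                 counties["land_area"].to_numpy())
        hd1 = population_density(counties[f"pop_{t1}"].to_numpy(),
                                 counties["land_area"].to_numpy())
        lam = growth_rate(hd0, hd1, t0, t1, form=form)
        h0, h1 = assign_horizon(t1, years)
        clim = normals[(normals["horizon_start"] == h0)
                       & (normals["horizon_end"] == h1)]
        clim = clim.set_index("county_id")
        block = pd.DataFrame({
            "county_id": counties["county_id"].to_numpy(),
            "x": counties["x"].to_numpy(),
            "y": counties["y"].to_numpy(),
            "t0": t0,
            "t1": t1,
            "lambda": lam,
            "log_density": log_density(hd0),
            "income_z": income_z[t0].to_numpy(),
            "ag_density": agricultural_density(
                counties[f"ag_{t0}"].to_numpy(),
                counties["land_area"].to_numpy()),
            "waterway_sqrt": waterway_sqrt(
                counties["waterway_dist"].to_numpy()),
        })
        for var in CLIMATIC_PREDICTORS:
            block[var] = clim[var].reindex(block["county_id"]).to_numpy()
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)

    pred_cols = list(ALL_PREDICTORS)
    bad = table[pred_cols + ["lambda"]].isna().any(axis=1)
    if bad.any():
        logger.warning("build_growth_table: dropping %d rows with missing "
                       "predictors", int(bad.sum()))
        table = table.loc[~bad].reset_index(drop=True)
    if table.empty:
        raise PipelineError("growth table is empty after predictor assembly")
    cols = ["county_id", "x", "y", "t0", "t1", "lambda"] + pred_cols
    return table[cols]
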