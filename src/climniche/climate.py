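"""Climate normals: four variables, 20-year horizons, IDW to county centroids.

From gridded monthly station series the module derives, per station-year,

* annual temperature — mean of the 12 monthly mean temperatures (degC),
* temperature seasonality — SD of the 12 monthly temperatures (degC),
* annual precipitation — sum of the 12 monthly totals (mm),
* precipitation seasonality — SD of the 12 monthly totals (mm),

averages the yearly values over each 20-year horizon, and interpolates the
horizon normals to county centroids with inverse distance weighting.
Seasonality uses the sample SD (n-1) by default; population SD is a switch.
Distances are planar Euclidean in the input coordinates (degrees for
geographic data); a haversine option exists for completeness.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, DomainError

logger = logging.getLogger(__name__)

CLIMATE_VARS = ("annual_temp", "temp_seasonality",
                "annual_precip", "precip_seasonality")


def yearly_climate(temps: Sequence[float], precips: Sequence[float],
                   ddof: int = 1) -> tuple:
    """Four climate summaries from one station-year of 12 monthly values."""
    t = np.asarray(temps, dtype=float)
    p = np.asarray(precips, dtype=float)
    if t.shape != (12,) or p.shape != (12,):
        raise DataError(f"need exactly 12 monthly values, got {t.size} temps "
                        f"and {p.size} precips")
    if np.any(p < 0):
        raise DataError("monthly precipitation must be nonnegative")
    return (float(t.mean()), float(t.std(ddof=ddof)),
            float(p.sum()), float(p.std(ddof=ddof)))


def yearly_climate_table(series: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per station-year climate summaries from a long monthly table.

    ``series`` columns: station_id, x, y, year, month, temp, precip.
    Raises :class:`DataError` naming the station-year if any has != 12 months.
    """
    counts = series.groupby(["station_id", "year"])["month"].nunique()
    bad = counts[counts != 12]
    if not bad.empty:
        sid, yr = bad.index[0]
        raise DataError(f"station {sid} year {yr} has {bad.iloc[0]} months "
                        "(12 required)")
    rows = []
    for (sid, yr), g in series.groupby(["station_id", "year"], sort=True):
        g = g.sort_values("month")
        at, ts, ap, ps = yearly_climate(g["temp"].to_numpy(),
                                        g["precip"].to_numpy(), ddof=ddof)
        rows.append((sid, g["x"].iloc[0], g["y"].iloc[0], yr, at, ts, ap, ps))
    return pd.DataFrame(rows, columns=["station_id", "x", "y", "year",
                                       *CLIMATE_VARS])


def horizon_average(yearly: pd.DataFrame, horizon: tuple) -> pd.DataFrame:
    """Average yearly climate values over an inclusive (start, end) horizon.

    Every year of the horizon must be present for every station.
    """
    start, end = horizon
    sel = yearly[(yearly["year"] >= start) & (yearly["year"] <= end)]
    n_years = end - start + 1
    counts = sel.groupby("station_id")["year"].nunique()
    bad = counts[counts != n_years]
    if not bad.empty or sel.empty:
        sid = bad.index[0] if not bad.empty else "<all>"
        raise DataError(f"horizon {start}-{end} incomplete for station {sid}")
    out = (sel.groupby("station_id", sort=True)
              .agg({"x": "first", "y": "first",
                    **{v: "mean" for v in CLIMATE_VARS}})
              .reset_index())
    out["horizon_start"] = start
    out["horizon_end"] = end
    return out


def _distances(points: np.ndarray, target: np.ndarray,
               metric: str = "euclidean") -> np.ndarray:
    if metric == "euclidean":
        return np.hypot(points[:, 0] - target[0], points[:, 1] - target[1])
    if metric == "haversine":
        r = 6371.0  # km
        lon1, lat1 = np.radians(points[:, 0]), np.radians(points[:, 1])
        lon2, lat2 = math.radians(target[0]), math.radians(target[1])
        dlat = lat2 - lat1
        dlon = lon2 - lon1
        a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * math.cos(lat2) * np.sin(dlon / 2) ** 2
        return 2 * r * np.arcsin(np.sqrt(a))
    raise ConfigurationError(f"unknown distance metric {metric!r}")


def idw_interpolate(stations_xy, values, target, power: float = 2.0,
                    metric: str = "euclidean") -> float:
    """Inverse-distance-weighted interpolation at one target point.

    Weights are ``d**-power`` over *all* stations (no cutoff radius).  A
    station coincident with the target returns that station's value exactly;
    the result is always within [min(values), max(values)].
    """
    pts = np.asarray(stations_xy, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    if pts.shape[0] == 0:
        raise DomainError("idw_interpolate needs at least one station")
    if power <= 0:
        raise DomainError("IDW power must be positive")
    d = _distances(pts, np.asarray(target, dtype=float), metric)
    hit = d == 0
    if hit.any():
        return float(vals[hit][0])
    w = d ** (-power)
    return float(np.dot(w, vals) / w.sum())


def interpolate_to_counties(station_normals: pd.DataFrame,
                            counties: pd.DataFrame,
                            power: float = 2.0,
                            metric: str = "euclidean") -> pd.DataFrame:
    """IDW-interpolate station horizon normals to every county centroid.

    Returns a table keyed by ``county_id, horizon_start, horizon_end`` with
    the four climate variables.  When a centroid coincides with a station the
    station's normals are reproduced exactly (IDW exactness at data points).
    """
    out_rows = []
    for (h0, h1), g in station_normals.groupby(["horizon_start",
                                                "horizon_end"], sort=True):
        pts = g[["x", "y"]].to_numpy(dtype=float)
        valmat = g[list(CLIMATE_VARS)].to_numpy(dtype=float)
        for _, c in counties.iterrows():
            target = (float(c["x"]), float(c["y"]))
            d = _distances(pts, np.asarray(target), metric)
            hit = np.flatnonzero(d == 0)
            if hit.size:
                vals = valmat[hit[0]]
            else:
                w = d ** (-power)
                vals = (w @ valmat) / w.sum()
            out_rows.append((c["county_id"], h0, h1, *vals))
    return pd.DataFrame(out_rows, columns=["county_id", "horizon_start",
                                           "horizon_end", *CLIMATE_VARS])


def assign_horizon(census_year: int,
                   census_years: Iterable[int] = (1900, 1920, 1940,
                                                 1960, 1980, 2000)) -> tuple:
    """20-year climate horizon ending at a census year.

    ``(census_year - 19, census_year)`` for every configured year except the
    first century census, which reuses the earliest available horizon
    (1900 -> (1901, 1920)): no instrumental record precedes the century, so
    the first two censuses share climate conditions.
    """
    years = sorted(census_years)
    if census_year not in years:
        raise ConfigurationError(f"census year {census_year} not in "
                                 f"configured set {years}")
    if census_year == years[0]:
        second = years[1]
        return (second - 19, second)
    return (census_year - 19, census_year)


def compute_normals(series: pd.DataFrame, counties: pd.DataFrame,
                    census_years: Sequence[int], power: float = 2.0,
                    ddof: int = 1, metric: str = "euclidean") -> pd.DataFrame:
    """Full climate stage: monthly series -> county x horizon normals."""
    yearly = yearly_climate_table(series, ddof=ddof)
    horizons = sorted({assign_horizon(y, census_years) for y in census_years})
    blocks = [horizon_average(yearly, h) for h in horizons]
    station_normals = pd.concat(blocks, ignore_index=True)
    return interpolate_to_counties(station_normals, counties,
                                   power=power, metric=metric)
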