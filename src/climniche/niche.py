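"""Climate exposure accounting and the realized climate-niche surface.

Two complementary views of a population's relationship with climate:

* *Climate change*: the unweighted county average of a climate variable —
  what the thermometer network says about the territory.
* *Climate exposure*: the population-weighted average — the climate
  experienced by the average person.  When growth concentrates in particular
  climates, exposure can move much faster than the territory's climate
  ("demographic amplification"); the ratio of the two endpoint changes
  quantifies the amplification.

The niche surface is the distribution of population over a 2-D climate space
(by default annual temperature x temperature seasonality): populations are
binned on a grid, log10(1+pop) is smoothed with a local quadratic (LOESS,
tricube weights, nearest ceil(alpha*N) cells), and peaks of the smoothed
surface are identified and tracked across census years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import DataError, DomainError, PipelineError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exposure accounting
# ---------------------------------------------------------------------------

def exposure_mean(values, weights) -> float:
    """Population-weighted mean of a climate variable.

    Exactly-uniform weights short-circuit to the unweighted mean so the
    identity exposure_mean == area_mean holds bit-exactly in that case.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise DomainError("values and weights must be equal-length vectors")
    if np.any(w < 0):
        raise DomainError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DomainError("total weight must be positive")
    if np.all(w == w[0]):
        return float(v.mean())
    return float(np.dot(w, v) / total)


def area_mean(values) -> float:
    """Unweighted mean over counties (the territory's average climate)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("area_mean of empty input")
    return float(v.mean())


@dataclass
class ExposureTrajectory:
    """Per-year exposure and area means plus endpoint deltas.

    ``table`` has one row per (year, variable) with columns
    ``exposure_mean, area_mean, area_valid``; ``area_valid`` is False for a
    census year that reuses another year's climate horizon (its area mean
    would duplicate that year's and is flagged rather than reported).
    ``deltas`` maps variable -> (delta_exposure, delta_area) between the
    configured endpoint years.
    """
    table: pd.DataFrame
    deltas: Dict[str, Tuple[float, float]]
    endpoints: Tuple[int, int]


def exposure_trajectory(normals: pd.DataFrame,
                        populations: pd.DataFrame,
                        census_years: Sequence[int],
                        variables: Sequence[str] = ("annual_temp",
                                                    "temp_seasonality"),
                        endpoints: Tuple[int, int] = (1920, 2000),
                        horizon_years: Optional[Sequence[int]] = None
                        ) -> ExposureTrajectory:
    """Exposure vs area means per census year for the given climate variables.

    Parameters
    ----------
    normals
        County x horizon climate normals (``county_id, horizon_start,
        horizon_end`` + variables).
    populations
        Wide table ``county_id, pop_<year>...`` for every census year.
    census_years
        Ordered census years.
    variables
        Climate variables to track.
    endpoints
        (start, end) years for the reported deltas.
    """
    from .climate import assign_horizon

    years = list(census_years)
    if horizon_years is None:
        horizon_years = years
    for y in years:
        if f"pop_{y}" not in populations.columns:
            raise PipelineError(f"populations table lacks pop_{y}")

    pops = populations.set_index("county_id")
    horizons = {y: assign_horizon(y, horizon_years) for y in years}
    # the first census shares the second census's horizon: flag its area mean
    shared = {y for y in years
              if y != min(years) and horizons[min(years)] == horizons[y]}
    rows = []
    for y in years:
        h0, h1 = horizons[y]
        clim = normals[(normals["horizon_start"] == h0)
                       & (normals["horizon_end"] == h1)].set_index("county_id")
        if clim.empty:
            raise PipelineError(f"no normals for horizon {h0}-{h1}")
        common = clim.index.intersection(pops.index)
        if len(common) == 0:
            raise PipelineError("normals and populations share no counties")
        w = pops.loc[common, f"pop_{y}"].to_numpy(dtype=float)
        area_valid = not (y == min(years) and shared)
        for var in variables:
            v = clim.loc[common, var].to_numpy(dtype=float)
            rows.append((y, var, exposure_mean(v, w),
                         area_mean(v) if area_valid else np.nan, area_valid))
    table = pd.DataFrame(rows, columns=["year", "variable", "exposure_mean",
                                        "area_mean", "area_valid"])

    a, b = endpoints
    deltas = {}
    for var in variables:
        sub = table[table["variable"] == var].set_index("year")
        de = sub.loc[b, "exposure_mean"] - sub.loc[a, "exposure_mean"]
        da = sub.loc[b, "area_mean"] - sub.loc[a, "area_mean"]
        deltas[var] = (float(de), float(da))
    return ExposureTrajectory(table=table, deltas=deltas, endpoints=(a, b))


def amplification_ratio(delta_exposure: float, delta_area: float) -> float:
    """How many times faster exposure changed than the area-mean climate.

    Returns NaN (with a log message) when the area change is zero — the
    ratio is undefined, not an error.
    """
    if delta_area == 0:
        logger.info("amplification ratio undefined: area-mean change is 0")
        return math.nan
    return delta_exposure / delta_area


# ---------------------------------------------------------------------------
# niche surface
# ---------------------------------------------------------------------------

@dataclass
class AxisSpec:
    """One climate axis of the niche grid: variable name, range, bin count."""
    name: str
    lo: float
    hi: float
    n_bins: int

    def __post_init__(self):
        if not self.lo < self.hi:
            raise DomainError(f"axis {self.name}: lo must be < hi")
        if self.n_bins < 2:
            raise DomainError(f"axis {self.name}: need at least 2 bins")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @classmethod
    def from_values(cls, name: str, values, n_bins: int = 50,
                    margin: float = 0.02) -> "AxisSpec":
        """Axis spanning the observed range plus a fractional margin."""
        v = np.asarray(values, dtype=float)
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        if span == 0:
            span = max(abs(lo), 1.0)
        pad = margin * span
        return cls(name, lo - pad, hi + pad, n_bins)


@dataclass
class NicheSurface:
    """Binned + smoothed population surface over 2-D climate space."""
    axis1: AxisSpec
    axis2: AxisSpec
    raw: np.ndarray            # [i, j]: population summed per cell
    smooth: Optional[np.ndarray] = None
    peaks: Optional[pd.DataFrame] = None


def bin_population(c1, c2, population, axis1: AxisSpec, axis2: AxisSpec,
                   policy: str = "strict") -> np.ndarray:
    """Sum county populations onto the climate grid.

    Cells are half-open [lo, hi) except the last, which is closed, so every
    in-range county lands in exactly one cell and the grid total equals the
    total in-range population (exact, since addition of counts is exact).
    ``policy``: "strict" errors on out-of-range counties; "drop" skips them.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    pop = np.asarray(population, dtype=float)
    if not (c1.shape == c2.shape == pop.shape):
        raise DomainError("c1, c2, population must be equal-length")
    in1 = (c1 >= axis1.lo) & (c1 <= axis1.hi)
    in2 = (c2 >= axis2.lo) & (c2 <= axis2.hi)
    ok = in1 & in2
    if not ok.all():
        if policy == "strict":
            raise DataError(f"{int((~ok).sum())} counties outside the grid "
                            "range (policy='strict')")
        c1, c2, pop = c1[ok], c2[ok], pop[ok]
    i = np.searchsorted(axis1.edges, c1, side="right") - 1
    j = np.searchsorted(axis2.edges, c2, side="right") - 1
    i = np.minimum(i, axis1.n_bins - 1)  # close the last cell
    j = np.minimum(j, axis2.n_bins - 1)
    grid = np.zeros((axis1.n_bins, axis2.n_bins))
    np.add.at(grid, (i, j), pop)
    return grid


def loess_surface(raw: np.ndarray, axis1: AxisSpec, axis2: AxisSpec,
                  alpha: float = 0.3, degree: int = 2) -> np.ndarray:
    """LOESS-smooth log10(1+population) over the climate grid.

    At each cell center a weighted least-squares polynomial of the two
    (range-normalized) climate coordinates is fitted to the nearest
    ceil(alpha*N) cells with tricube weights and evaluated at the center.
    degree 2 (full quadratic) by default; cells with too few positively
    weighted neighbours for the quadratic fall back to linear, then to a
    weighted mean, with a warning.
    """
    if not 0 < alpha <= 1:
        raise DomainError("alpha must be in (0, 1]")
    if degree not in (0, 1, 2):
        raise DomainError("degree must be 0, 1 or 2")
    n1, n2 = raw.shape
    if (n1, n2) != (axis1.n_bins, axis2.n_bins):
        raise DomainError("raw grid shape does not match axes")
    z = np.log10(1.0 + raw).ravel()
    # normalize coordinates by axis range so the two climate units are
    # commensurable in the distance metric
    cx = (axis1.centers - axis1.lo) / (axis1.hi - axis1.lo)
    cy = (axis2.centers - axis2.lo) / (axis2.hi - axis2.lo)
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    N = pts.shape[0]
    k = max(2, math.ceil(alpha * N))
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=k)
    out = np.empty(N)
    n_fallback = 0
    for c in range(N):
        d = dist[c]
        nb = idx[c]
        dmax = d[-1]
        if dmax == 0:
            w = np.ones_like(d)
        else:
            w = (1.0 - (d / dmax) ** 3) ** 3
        pos = w > 0
        xs = pts[nb[pos]] - pts[c]          # center local coordinates
        ws = w[pos]
        zs = z[nb[pos]]
        deg = degree
        while True:
            if deg == 2 and pos.sum() >= 6:
                A = np.column_stack([np.ones(len(xs)), xs[:, 0], xs[:, 1],
                                     xs[:, 0] ** 2, xs[:, 0] * xs[:, 1],
                                     xs[:, 1] ** 2])
            elif deg >= 1 and pos.sum() >= 3:
                if deg == 2:
                    n_fallback += 1
                deg = 1
                A = np.column_stack([np.ones(len(xs)), xs[:, 0], xs[:, 1]])
            else:
                if deg > 0:
                    n_fallback += 1
                out[c] = float(np.dot(ws, zs) / ws.sum())
                break
            sw = np.sqrt(ws)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], zs * sw, rcond=None)
            val = coef[0]                    # polynomial at the local origin
            if np.isfinite(val):
                out[c] = float(val)
                break
            deg -= 1                         # numerically bad: step down
    if n_fallback:
        logger.warning("loess_surface: %d cells fell back to a lower degree",
                       n_fallback)
    return out.reshape(n1, n2)


def find_peaks(smooth: np.ndarray, min_separation: float = 3.0,
               min_height: float = -math.inf,
               axis1: Optional[AxisSpec] = None,
               axis2: Optional[AxisSpec] = None) -> pd.DataFrame:
    """Strict local maxima of the smoothed surface, greedily thinned.

    A cell is a peak candidate when its value strictly exceeds all its
    existing 8-neighbours and is >= ``min_height``.  Candidates are sorted by
    height (descending) and kept only if at least ``min_separation`` cells
    (Euclidean, in cell indices) from every already-kept peak.

    Returns a DataFrame ``row, col, height`` plus climate coordinates
    ``c1, c2`` when axes are supplied, sorted by height descending.
    """
    s = np.asarray(smooth, dtype=float)
    n1, n2 = s.shape
    cands = []
    # interior cells only: a boundary maximum of a monotone surface is an
    # artifact of the grid edge, not a niche peak
    for i in range(1, n1 - 1):
        for j in range(1, n2 - 1):
            v = s[i, j]
            if v < min_height:
                continue
            neigh = s[i - 1:i + 2, j - 1:j + 2]
            if (neigh >= v).sum() == 1:  # only the center itself reaches v
                cands.append((v, i, j))
    cands.sort(reverse=True)
    kept: List[Tuple[float, int, int]] = []
    for v, i, j in cands:
        if all(math.hypot(i - ki, j - kj) >= min_separation
               for _, ki, kj in kept):
            kept.append((v, i, j))
    rows = []
    for v, i, j in kept:
        rec = {"row": i, "col": j, "height": v}
        if axis1 is not None:
            rec["c1"] = float(axis1.centers[i])
        if axis2 is not None:
            rec["c2"] = float(axis2.centers[j])
        rows.append(rec)
    cols = ["row", "col", "height"] + (["c1"] if axis1 is not None else []) \
        + (["c2"] if axis2 is not None else [])
    return pd.DataFrame(rows, columns=cols)


def build_surface(c1, c2, population, axis1: AxisSpec, axis2: AxisSpec,
                  alpha: float = 0.3, degree: int = 2,
                  min_separation: float = 3.0,
                  min_height: float = -math.inf,
                  policy: str = "strict") -> NicheSurface:
    """Bin, smooth, and peak-find in one call."""
    raw = bin_population(c1, c2, population, axis1, axis2, policy=policy)
    smooth = loess_surface(raw, axis1, axis2, alpha=alpha, degree=degree)
    peaks = find_peaks(smooth, min_separation=min_separation,
                       min_height=min_height, axis1=axis1, axis2=axis2)
    return NicheSurface(axis1=axis1, axis2=axis2, raw=raw,
                        smooth=smooth, peaks=peaks)


def peak_abundance_series(surfaces: Dict[int, NicheSurface],
                          radius: float) -> pd.DataFrame:
    """Track niche peaks across census years and sum abundance around them.

    Peaks are matched year-to-year by nearest neighbour in (range-normalized)
    climate space within ``radius`` (same normalized units); an unmatched new
    peak starts a new lineage (logged).  Per year, a lineage's abundance is
    the raw population summed over grid cells whose centers lie within
    ``radius`` of the matched peak.

    Returns a long DataFrame ``year, lineage, c1, c2, height, abundance``.
    """
    years = sorted(surfaces)
    if not years:
        raise PipelineError("no surfaces supplied")

    def norm_coords(surf: NicheSurface, df: pd.DataFrame) -> np.ndarray:
        u = (df["c1"].to_numpy() - surf.axis1.lo) / (surf.axis1.hi - surf.axis1.lo)
        v = (df["c2"].to_numpy() - surf.axis2.lo) / (surf.axis2.hi - surf.axis2.lo)
        return np.column_stack([u, v])

    lineages: List[np.ndarray] = []        # last known normalized position
    records = []
    for year in years:
        surf = surfaces[year]
        if surf.peaks is None or surf.smooth is None:
            raise PipelineError(f"surface for {year} lacks peaks")
        pk = surf.peaks.reset_index(drop=True)
        pos = norm_coords(surf, pk) if len(pk) else np.empty((0, 2))
        assigned = {}
        taken = set()
        # match current peaks (height order) to existing lineages
        for p in range(len(pk)):
            best, bestd = None, radius
            for li, lpos in enumerate(lineages):
                if li in taken:
                    continue
                d = float(np.hypot(*(pos[p] - lpos)))
                if d <= bestd:
                    best, bestd = li, d
            if best is None:
                lineages.append(pos[p].copy())
                best = len(lineages) - 1
                if year != years[0]:
                    logger.info("peak_abundance_series: new lineage %d in %d",
                                best, year)
            else:
                lineages[best] = pos[p].copy()
            taken.add(best)
            assigned[p] = best
        # abundance within radius of each matched peak
        cx = (surf.axis1.centers - surf.axis1.lo) / (surf.axis1.hi - surf.axis1.lo)
        cy = (surf.axis2.centers - surf.axis2.lo) / (surf.axis2.hi - surf.axis2.lo)
        U, V = np.meshgrid(cx, cy, indexing="ij")
        for p, li in assigned.items():
            d = np.hypot(U - pos[p][0], V - pos[p][1])
            abundance = float(surf.raw[d <= radius].sum())
            records.append((year, li, float(pk.loc[p, "c1"]),
                            float(pk.loc[p, "c2"]),
                            float(pk.loc[p, "height"]), abundance))
    return pd.DataFrame(records, columns=["year", "lineage", "c1", "c2",
                                          "height", "abundance"])
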