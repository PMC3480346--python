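"""Geographically weighted regression with adaptive bi-square kernels.

GWR fits one weighted least-squares regression per location i,

    beta_i = (X' W_i X)^-1 X' W_i y,

where W_i is diagonal with bi-square weights w = (1 - (d/b_i)^2)^2 for
d < b_i and 0 beyond.  The bandwidth b_i is adaptive: the distance from
location i to its k-th nearest other location, k = ceil(fraction * (n-1)),
so every local fit uses the same *share* of neighbours regardless of local
density (a fixed-distance kernel would starve coastal/edge locations).

Model quality is summarized with the small-sample corrected AIC for
nonparametric regressions,

    AICc = n ln(RSS/n) + n ln(2*pi) + n (n + tr S) / (n - 2 - tr S),

where tr S, the trace of the hat matrix (sum over locations of
w_i(0) * x_i' (X' W_i X)^-1 x_i), is the model's effective number of
parameters.  Akaike weights over a model set convert AICc differences to
normalized evidence.

Standardized coefficients (stdbeta) come from regressing the z-scored
response on z-scored predictors; a county's most important predictor is the
one with the largest |stdbeta| there, and the share of counties voting for
each predictor is the relative-importance summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import (
    BandwidthError,
    CollinearityError,
    ConfigurationError,
    DegenerateInputError,
    DomainError,
)
from .demography import ALL_PREDICTORS, CLIMATIC_PREDICTORS, NONCLIMATIC_PREDICTORS

logger = logging.getLogger(__name__)

CONDITION_LIMIT = 1e10


@dataclass
class KernelSpec:
    """Geographical weighting kernel.

    kind: "bisquare" (default) or "uniform" (w=1 within the bandwidth; with
    fraction 1 this makes GWR collapse to global OLS).
    fraction: adaptive share of neighbours defining the bandwidth.
    fallback_fractions: wider fractions tried, in order, when a local design
    is ill-conditioned at the base fraction.
    """
    kind: str = "bisquare"
    fraction: float = 0.3
    fallback_fractions: Tuple[float, ...] = (0.45, 0.5)

    def __post_init__(self):
        if self.kind not in ("bisquare", "uniform"):
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        if not 0 < self.fraction <= 1:
            raise ConfigurationError("fraction must be in (0, 1]")
        fb = tuple(self.fallback_fractions)
        if any(not 0 < f <= 1 for f in fb):
            raise ConfigurationError("fallback fractions must be in (0, 1]")
        if any(b <= a for a, b in zip((self.fraction,) + fb, fb)):
            raise ConfigurationError("fallback fractions must be strictly "
                                     "increasing from the base fraction")
        self.fallback_fractions = fb


def bisquare_weight(d, b: float):
    """Bi-square kernel: (1 - (d/b)^2)^2 inside the bandwidth, 0 outside."""
    if b <= 0:
        raise DomainError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("distance must be nonnegative")
    u = d / b
    out = np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return float(out) if out.ndim == 0 else out


def uniform_weight(d, b: float):
    """Box kernel: 1 for d <= b, else 0 (closed at the bandwidth so that
    fraction 1 includes every point with full weight)."""
    if b <= 0:
        raise DomainError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    out = np.where(d <= b, 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def adaptive_bandwidth(coords: np.ndarray, i: int, fraction: float,
                       dist_row: Optional[np.ndarray] = None) -> float:
    """Distance from location i to its k-th nearest *other* location,
    k = ceil(fraction * (n-1))."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise DomainError("need at least 2 locations")
    if not 0 < fraction <= 1:
        raise DomainError("fraction must be in (0, 1]")
    if dist_row is None:
        dist_row = np.hypot(coords[:, 0] - coords[i, 0],
                            coords[:, 1] - coords[i, 1])
    others = np.delete(dist_row, i)
    k = math.ceil(fraction * (n - 1))
    b = float(np.partition(others, k - 1)[k - 1])
    if b <= 0:
        raise BandwidthError(f"bandwidth at location {i} is 0 "
                             "(duplicate coordinates)")
    return b


def local_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
              x0: Optional[np.ndarray] = None,
              location: int = -1) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Weighted least squares at one location.

    Returns the coefficient vector and, when the focal design row ``x0`` is
    given, the hat row x0' (X'WX)^-1 X'W (length n).  Raises
    :class:`CollinearityError` carrying ``location`` when X'WX has condition
    number above 1e10.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p = X.shape[1]
    if int((w > 0).sum()) < p:
        raise CollinearityError(location, math.inf)
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    cond = np.linalg.cond(XtWX)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise CollinearityError(location, cond)
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    hat_row = None
    if x0 is not None:
        hat_row = np.linalg.solve(XtWX, np.asarray(x0, dtype=float))
        hat_row = Xw @ hat_row  # (X'W)' (X'WX)^-1 x0, length n
    return beta, hat_row


@dataclass
class GWRFit:
    """One fitted GWR model."""
    predictor_names: Tuple[str, ...]      # excludes the intercept
    coords: np.ndarray
    coef: np.ndarray                      # n x (p+1), column 0 = intercept
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    bandwidths: np.ndarray
    fractions_used: np.ndarray
    kernel: KernelSpec
    rss: float
    enp: float
    aicc: float
    meta: Dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.fitted)

    def coef_frame(self) -> pd.DataFrame:
        cols = ("intercept",) + tuple(self.predictor_names)
        return pd.DataFrame(self.coef, columns=cols)


def fit_gwr(X: np.ndarray, y: np.ndarray, coords: np.ndarray,
            kernel: Optional[KernelSpec] = None,
            predictor_names: Optional[Sequence[str]] = None,
            add_intercept: bool = True) -> GWRFit:
    """Fit one local regression per location.

    X (n x p, without intercept unless ``add_intercept=False``), y (n),
    coords (n x 2, planar).  Any location whose local design is
    ill-conditioned at the base fraction is retried at the kernel's fallback
    fractions (logged); if all fail, the error lists the offending locations.
    """
    if kernel is None:
        kernel = KernelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = X.shape[0]
    if y.shape != (n,) or coords.shape != (n, 2):
        raise DomainError("X, y, coords must have matching lengths")
    if predictor_names is None:
        predictor_names = tuple(f"x{j}" for j in range(X.shape[1]))
    design = np.column_stack([np.ones(n), X]) if add_intercept else X
    p = design.shape[1]

    D = cdist(coords, coords)
    wfun = bisquare_weight if kernel.kind == "bisquare" else uniform_weight
    fractions = (kernel.fraction,) + kernel.fallback_fractions

    coef = np.empty((n, p))
    fitted = np.empty(n)
    hat_diag = np.empty(n)
    bandwidths = np.empty(n)
    fractions_used = np.empty(n)
    failed: List[int] = []
    n_retries = 0
    for i in range(n):
        done = False
        for fi, frac in enumerate(fractions):
            b = adaptive_bandwidth(coords, i, frac, dist_row=D[i])
            w = wfun(D[i], b)
            try:
                beta, hat_row = local_fit(design, y, w, x0=design[i],
                                          location=i)
            except CollinearityError:
                n_retries += fi < len(fractions) - 1
                continue
            coef[i] = beta
            fitted[i] = design[i] @ beta
            hat_diag[i] = hat_row[i]
            bandwidths[i] = b
            fractions_used[i] = frac
            if fi > 0:
                logger.info("fit_gwr: location %d used fallback fraction %g",
                            i, frac)
            done = True
            break
        if not done:
            failed.append(i)
    if failed:
        raise CollinearityError(failed[0], math.inf) from None

    residuals = y - fitted
    rss = float(residuals @ residuals)
    enp = effective_parameters(hat_diag)
    aicc = gwr_aicc(rss, n, enp)
    return GWRFit(predictor_names=tuple(predictor_names), coords=coords,
                  coef=coef, fitted=fitted, residuals=residuals,
                  hat_diag=hat_diag, bandwidths=bandwidths,
                  fractions_used=fractions_used, kernel=kernel,
                  rss=rss, enp=enp, aicc=aicc,
                  meta={"aicc_variant":
                        "n ln(RSS/n) + n ln(2pi) + n(n+trS)/(n-2-trS)",
                        "enp_definition": "trace of hat matrix"})


@dataclass
class ScalingRecord:
    """Means/SDs used to z-score the design, for raw-scale recovery."""
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    predictor_names: Tuple[str, ...]

    def raw_coefficients(self, std_coef: np.ndarray) -> np.ndarray:
        """Map standardized coefficients (incl. intercept) back to raw scale.

        Accepts one coefficient vector or an n x (p+1) matrix of local ones.
        """
        std_coef = np.atleast_2d(np.asarray(std_coef, dtype=float))
        slopes = std_coef[:, 1:] * self.y_sd / self.x_sd
        intercept = (self.y_mean + self.y_sd * std_coef[:, 0]
                     - slopes @ self.x_mean)
        out = np.column_stack([intercept, slopes])
        return out[0] if out.shape[0] == 1 else out


def standardize_design(table: pd.DataFrame,
                       predictors: Sequence[str] = ALL_PREDICTORS,
                       response: str = "lambda"
                       ) -> Tuple[np.ndarray, np.ndarray, ScalingRecord]:
    """Z-score predictors and response (sample SD) over the rows of one
    interval's growth table, so fitted coefficients are stdbeta."""
    if len(table) < 2:
        raise DegenerateInputError("need at least 2 rows to standardize")
    Xraw = table[list(predictors)].to_numpy(dtype=float)
    yraw = table[response].to_numpy(dtype=float)
    x_mean = Xraw.mean(axis=0)
    x_sd = Xraw.std(axis=0, ddof=1)
    zero = np.flatnonzero(x_sd == 0)
    if zero.size:
        raise DegenerateInputError(
            f"predictor {predictors[zero[0]]!r} has zero variance")
    y_sd = yraw.std(ddof=1)
    if y_sd == 0:
        raise DegenerateInputError("response has zero variance")
    X = (Xraw - x_mean) / x_sd
    y = (yraw - yraw.mean()) / y_sd
    rec = ScalingRecord(x_mean=x_mean, x_sd=x_sd, y_mean=float(yraw.mean()),
                        y_sd=float(y_sd), predictor_names=tuple(predictors))
    return X, y, rec


def effective_parameters(hat_diag) -> float:
    """Effective number of parameters: trace of the hat matrix."""
    return float(np.asarray(hat_diag, dtype=float).sum())


def gwr_aicc(rss: float, n: int, enp: float) -> float:
    """Small-sample corrected AIC for a model with effective parameters enp."""
    if rss <= 0:
        raise DomainError("rss must be positive")
    if n <= enp + 2:
        raise DomainError(f"AICc undefined: n={n} <= enp+2={enp + 2}")
    return float(n * math.log(rss / n) + n * math.log(2 * math.pi)
                 + n * (n + enp) / (n - 2 - enp))


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Normalized evidence weights exp(-Delta/2)/sum over a model set."""
    a = np.asarray(aiccs, dtype=float)
    if a.size < 2:
        raise DomainError("need at least 2 models")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class RelativeImportance:
    """Per-predictor vote shares from max-|stdbeta| county votes."""
    counts: Dict[str, int]
    n: int
    n_ties: int
    grouping: Dict[str, str]

    @property
    def proportions(self) -> Dict[str, Fraction]:
        return {k: Fraction(v, self.n) for k, v in self.counts.items()}

    @property
    def group_proportions(self) -> Dict[str, Fraction]:
        out: Dict[str, Fraction] = {}
        for name, frac in self.proportions.items():
            g = self.grouping[name]
            out[g] = out.get(g, Fraction(0)) + frac
        return out

    def as_series(self) -> pd.Series:
        return pd.Series({k: float(v) for k, v in self.proportions.items()})


DEFAULT_GROUPING = {**{p: "climatic" for p in CLIMATIC_PREDICTORS},
                    **{p: "non-climatic" for p in NONCLIMATIC_PREDICTORS}}


def relative_importance(std_beta: pd.DataFrame,
                        grouping: Optional[Mapping[str, str]] = None
                        ) -> RelativeImportance:
    """Share of counties where each predictor has the largest |stdbeta|.

    Ties (measure-zero for continuous data) go to the first predictor in
    column order and are counted and logged.  Count arithmetic is exact, so
    the proportions sum to exactly 1.
    """
    if std_beta.isna().any().any():
        raise DomainError("std_beta contains missing values")
    names = list(std_beta.columns)
    if grouping is None:
        grouping = {n: DEFAULT_GROUPING.get(n, "non-climatic") for n in names}
    A = np.abs(std_beta.to_numpy(dtype=float))
    winners = A.argmax(axis=1)  # argmax takes the first maximum: tie rule
    n_ties = int(((A == A.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("relative_importance: %d tied counties assigned by "
                    "canonical order", n_ties)
    counts = {name: int((winners == j).sum()) for j, name in enumerate(names)}
    return RelativeImportance(counts=counts, n=len(std_beta), n_ties=n_ties,
                              grouping=dict(grouping))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

MODEL_NAMES = ("OLS_C+NC", "GWR_C", "GWR_NC", "GWR_C+NC")

#: wider bandwidths for the non-climate-only model in the early intervals,
#: where spatial collinearity among the non-climate predictors is strongest
DEFAULT_NC_FRACTION_OVERRIDES = {1900: 0.5, 1920: 0.5, 1940: 0.45}


@dataclass
class ModelComparison:
    table: pd.DataFrame                   # model, aicc, enp, akaike_weight
    fits: Dict[str, object]

    def best(self) -> str:
        return self.table.loc[self.table["akaike_weight"].idxmax(), "model"]


def _ols_fit(X: np.ndarray, y: np.ndarray):
    """Global OLS via statsmodels (the stationary baseline)."""
    import statsmodels.api as sm
    n = len(y)
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    rss = float(model.ssr)
    enp = float(X.shape[1] + 1)
    return model, rss, enp


def compare_models(table: pd.DataFrame, coords: np.ndarray,
                   fraction: float = 0.3,
                   nc_fraction_overrides: Optional[Mapping[int, float]] = None,
                   kernel_kind: str = "bisquare",
                   fallback_fractions: Tuple[float, ...] = (0.45, 0.5),
                   interval_start: Optional[int] = None) -> ModelComparison:
    """AICc comparison of the four-model suite on one interval's growth table.

    Models: global OLS with all 8 predictors, GWR with climate predictors
    only (C), non-climate only (NC), and all 8 (C+NC).  The NC model's
    kernel fraction may be overridden per interval (by its start year);
    the default overrides widen it for the three early-century intervals.
    """
    if nc_fraction_overrides is None:
        nc_fraction_overrides = DEFAULT_NC_FRACTION_OVERRIDES
    if interval_start is None and "t0" in table.columns:
        starts = table["t0"].unique()
        if len(starts) != 1:
            raise ConfigurationError("compare_models expects one interval")
        interval_start = int(starts[0])
    nc_fraction = nc_fraction_overrides.get(interval_start, fraction) \
        if interval_start is not None else fraction

    coords = np.asarray(coords, dtype=float)
    specs = {
        "GWR_C": (CLIMATIC_PREDICTORS, fraction),
        "GWR_NC": (NONCLIMATIC_PREDICTORS, nc_fraction),
        "GWR_C+NC": (ALL_PREDICTORS, fraction),
    }
    fits: Dict[str, object] = {}
    rows = []

    X_all, y, _ = standardize_design(table, ALL_PREDICTORS)
    ols, rss, enp = _ols_fit(X_all, y)
    n = len(y)
    fits["OLS_C+NC"] = ols
    rows.append(("OLS_C+NC", gwr_aicc(rss, n, enp), enp))

    for name, (preds, frac) in specs.items():
        Xm, ym, _ = standardize_design(table, preds)
        fb = tuple(f for f in fallback_fractions if f > frac)
        fit = fit_gwr(Xm, ym, coords,
                      kernel=KernelSpec(kind=kernel_kind, fraction=frac,
                                        fallback_fractions=fb),
                      predictor_names=preds)
        fits[name] = fit
        rows.append((name, fit.aicc, fit.enp))

    tab = pd.DataFrame(rows, columns=["model", "aicc", "enp"])
    tab["akaike_weight"] = akaike_weights(tab["aicc"].to_numpy())
    return ModelComparison(table=tab, fits=fits)
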