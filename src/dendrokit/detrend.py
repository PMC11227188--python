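"""Standardization of ring-width series and site-chronology statistics.

The growth trend is removed with a cubic smoothing spline whose
amplitude frequency response equals a chosen fraction (default 50%) at a
chosen wavelength (default 30 years).  Series are expressed as
dimensionless indices (ratio or difference), optionally prewhitened with
an AR model, and combined into a site chronology with Tukey's biweight
robust mean.  Chronology quality is summarised by mean sensitivity (MS),
mean interseries correlation (Rbar) and the expressed population signal
(EPS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from .rwl import RingWidthSeries, WoodComponent

__all__ = [
    "IndexMode",
    "DetrendConfig",
    "IndexSeries",
    "Chronology",
    "ChronologyStats",
    "fit_frequency_cutoff_spline",
    "standardize",
    "prewhiten_ar",
    "biweight_mean",
    "build_chronology",
    "mean_sensitivity",
    "interseries_rbar",
    "eps",
]

logger = logging.getLogger(__name__)


class IndexMode(str, Enum):
    RATIO = "RATIO"
    DIFFERENCE = "DIFFERENCE"


@dataclass(frozen=True)
class DetrendConfig:
    """Settings for standardization and chronology building."""

    spline_wavelength: float = 30.0
    cutoff_response: float = 0.5
    index_mode: IndexMode = IndexMode.RATIO
    prewhiten: bool = False
    ar_max_order: int = 3
    biweight_c: float = 9.0
    min_depth: int = 1
    fitted_floor: float = 0.001  # mm; guards ratio division

    def __post_init__(self) -> None:
        if self.spline_wavelength < 2:
            raise ValueError("spline_wavelength must be >= 2 years")
        if not 0 < self.cutoff_response < 1:
            raise ValueError("cutoff_response must be in (0, 1)")
        object.__setattr__(self, "index_mode", IndexMode(self.index_mode))


@dataclass
class IndexSeries:
    """Dimensionless detrended index series for one tree/core."""

    series_id: str
    first_year: int
    indices: np.ndarray
    component: WoodComponent = WoodComponent.TOTAL
    config: DetrendConfig | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=float)
        if self.indices.ndim != 1 or self.indices.size == 0:
            raise ValueError("indices must be a non-empty 1-d array")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.indices) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def value_at(self, year: int) -> float:
        if not self.first_year <= year <= self.last_year:
            return float("nan")
        return float(self.indices[year - self.first_year])

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ChronologyStats:
    ms: float
    rbar: float
    eps: float
    common_period: tuple[int, int] | None
    n_series: int


@dataclass
class Chronology:
    """Robust-mean site index chronology with per-year sample depth."""

    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray
    component: WoodComponent = WoodComponent.TOTAL
    stats: ChronologyStats | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        self.sample_depth = np.asarray(self.sample_depth, dtype=int)
        if not (len(self.years) == len(self.index) == len(self.sample_depth)):
            raise ValueError("years, index and sample_depth must have equal length")

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    def __len__(self) -> int:
        return len(self.years)

    def as_index_series(self, series_id: str = "CHRON") -> IndexSeries:
        if np.any(np.diff(self.years) != 1):
            raise ValueError("chronology years are not contiguous")
        return IndexSeries(series_id=series_id, first_year=self.first_year,
                           indices=self.index, component=self.component)


# ---------------------------------------------------------------------------
# smoothing spline with frequency-response parameterization

def _spline_lambda(wavelength: float, cutoff_response: float) -> float:
    # discrete cubic smoother: response H(w) = 1 / (1 + lam * (2 sin(w/2))^4);
    # solve H(2*pi/wavelength) = cutoff_response for lam
    omega = 2.0 * np.pi / wavelength
    return (1.0 - cutoff_response) / (cutoff_response * (2.0 * np.sin(omega / 2.0)) ** 4)


def fit_frequency_cutoff_spline(
    values: Sequence[float],
    wavelength: float = 30.0,
    cutoff_response: float = 0.5,
) -> np.ndarray:
    """Fit a cubic smoothing spline tuned by its frequency response.

    The smoothing parameter is chosen so that a sinusoid with period
    ``wavelength`` (in sample steps) is attenuated to ``cutoff_response``
    of its amplitude; longer periods pass through, shorter ones are
    suppressed.  Returns the fitted curve, same length as the input.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("need at least 4 values to fit the spline")
    if np.any(~np.isfinite(y)):
        raise ValueError("values must be finite")
    if wavelength < 2:
        raise ValueError("wavelength must be >= 2 samples")
    if not 0 < cutoff_response < 1:
        raise ValueError("cutoff_response must be in (0, 1)")

    n = len(y)
    lam = _spline_lambda(wavelength, cutoff_response)
    # second-difference penalty matrix; natural boundary behaviour
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    a = sp.eye(n, format="csc") + lam * (d2.T @ d2)
    fitted = spla.spsolve(a, y)
    return np.asarray(fitted)


def standardize(series: RingWidthSeries, config: DetrendConfig | None = None) -> IndexSeries:
    """Detrend one raw series into a dimensionless index series.

    RATIO mode divides by the fitted growth curve (clamped at a small
    floor); DIFFERENCE mode subtracts it.  Zero rings give index 0.
    """
    config = config or DetrendConfig()
    y = np.asarray(series.values, dtype=float)
    if len(y) < 4:
        raise ValueError(f"series {series.series_id!r}: need >= 4 rings to standardize")
    if np.all(y == 0):
        raise ValueError(f"series {series.series_id!r}: all rings are zero")
    fitted = fit_frequency_cutoff_spline(y, config.spline_wavelength, config.cutoff_response)
    if config.index_mode is IndexMode.RATIO:
        fitted = np.maximum(fitted, config.fitted_floor)
        indices = y / fitted
    else:
        indices = y - fitted
    return IndexSeries(
        series_id=series.series_id,
        first_year=series.first_year,
        indices=indices,
        component=series.component,
        config=config,
    )


# ---------------------------------------------------------------------------
# AR prewhitening

def prewhiten_ar(index: IndexSeries, max_order: int = 3) -> IndexSeries:
    """Remove autocorrelation by fitting AR(p), p chosen by AIC over 0..max_order.

    Returns the residual series re-centred to mean 1 (ratio-index
    convention).  The first ``p`` years are dropped.  A failed fit falls
    back to p = 0 (input returned unchanged) with a logged warning.
    """
    x = np.asarray(index.indices, dtype=float)
    if len(x) <= max_order + 10:
        raise ValueError("series too short for prewhitening (need > max_order + 10)")
    if np.ptp(x) == 0 or max_order == 0:
        return index

    try:
        from statsmodels.tsa.ar_model import AutoReg, ar_select_order

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = ar_select_order(x, maxlag=max_order, ic="aic", trend="c", old_names=False)
            lags = sel.ar_lags
            p = max(lags) if lags else 0
            if p == 0:
                return index
            fit = AutoReg(x, lags=p, trend="c", old_names=False).fit()
        resid = np.asarray(fit.resid, dtype=float)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("AR prewhitening failed for %s (%s); returning input", index.series_id, exc)
        return index

    resid = resid - resid.mean() + 1.0
    return replace(index, first_year=index.first_year + p, indices=resid)


# ---------------------------------------------------------------------------
# robust mean

def biweight_mean(values: Sequence[float], c: float = 9.0, tol: float = 1e-8,
                  max_iter: int = 200) -> float:
    """Tukey's biweight location estimate with MAD scale.

    Iterated to convergence ``|delta| < tol``.  Degenerate cases: n <= 2
    returns the arithmetic mean; zero MAD returns the median (the sample
    majority value).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight_mean of empty input")
    if x.size <= 2:
        return float(np.mean(x))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    t = med
    for _ in range(max_iter):
        u = (x - t) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w.sum() == 0:
            return float(med)
        t_new = float(np.sum(w * x) / np.sum(w))
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


# ---------------------------------------------------------------------------
# chronology statistics

def mean_sensitivity(x: Sequence[float]) -> float:
    """Classical mean sensitivity: average |2(x[t+1]-x[t]) / (x[t+1]+x[t])|.

    Pairs whose sum is zero (e.g. two missing rings) are skipped.
    Scale-invariant: MS(k*x) == MS(x) for k > 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("mean_sensitivity needs at least 2 values")
    a, b = x[:-1], x[1:]
    denom = a + b
    keep = np.isfinite(denom) & (denom != 0)
    if not np.any(keep):
        return 0.0
    terms = np.abs(2.0 * (b[keep] - a[keep]) / denom[keep])
    return float(terms.sum() / (len(x) - 1))


def interseries_rbar(
    indices: Sequence[IndexSeries],
    period: tuple[int, int] | None = None,
    min_overlap: int = 20,
) -> float:
    """Mean pairwise Pearson correlation over each pair's year overlap.

    Pairs with fewer than ``min_overlap`` overlapping years are skipped;
    years where both members are 0 (paired missing rings) are dropped.
    """
    if len(indices) < 2:
        raise ValueError("interseries_rbar needs at least 2 series")
    correlations = []
    for s1, s2 in combinations(indices, 2):
        lo = max(s1.first_year, s2.first_year)
        hi = min(s1.last_year, s2.last_year)
        if period is not None:
            lo, hi = max(lo, period[0]), min(hi, period[1])
        if hi - lo + 1 < min_overlap:
            continue
        a = s1.indices[lo - s1.first_year: hi - s1.first_year + 1]
        b = s2.indices[lo - s2.first_year: hi - s2.first_year + 1]
        keep = np.isfinite(a) & np.isfinite(b) & ~((a == 0) & (b == 0))
        if keep.sum() < min_overlap:
            continue
        aa, bb = a[keep], b[keep]
        if np.ptp(aa) == 0 or np.ptp(bb) == 0:
            continue
        r, _ = stats.pearsonr(aa, bb)
        correlations.append(r)
    if not correlations:
        raise ValueError("no series pair with sufficient overlap")
    return float(np.mean(correlations))


def eps(rbar: float, n: int) -> float:
    """Expressed population signal: n*rbar / (n*rbar + (1 - rbar))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1 < rbar <= 1:
        raise ValueError("rbar must be in (-1, 1]")
    denom = n * rbar + (1.0 - rbar)
    if denom <= 0:
        warnings.warn("EPS denominator <= 0 (strongly negative rbar); reporting 0")
        return 0.0
    value = n * rbar / denom
    return float(min(max(value, 0.0), 1.0))


def build_chronology(
    indices: Sequence[IndexSeries],
    min_depth: int = 1,
    biweight_c: float = 9.0,
    min_overlap: int = 20,
) -> Chronology:
    """Combine index series into a site chronology by per-year biweight mean.

    Years with fewer than ``min_depth`` contributing series are dropped.
    Chronology statistics (MS, Rbar, EPS, common period) are attached;
    Rbar/EPS are NaN when fewer than 2 series overlap enough.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("no index series given")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    lo = min(s.first_year for s in indices)
    hi = max(s.last_year for s in indices)
    years, chron, depth = [], [], []
    for year in range(lo, hi + 1):
        vals = [s.value_at(year) for s in indices]
        vals = [v for v in vals if np.isfinite(v)]
        if len(vals) < min_depth:
            continue
        years.append(year)
        chron.append(biweight_mean(vals, c=biweight_c))
        depth.append(len(vals))
    if not years:
        raise ValueError("no year reaches the requested sample depth")
    years = np.array(years)
    chron = np.array(chron)
    depth = np.array(depth)

    ms = mean_sensitivity(chron) if len(chron) >= 2 else float("nan")
    try:
        rbar = interseries_rbar(indices, min_overlap=min_overlap)
        eps_val = eps(rbar, len(indices))
    except ValueError:
        rbar = float("nan")
        eps_val = float("nan")
    common = None
    common_years = years[depth >= 2] if len(indices) > 1 else years
    if common_years.size:
        common = (int(common_years.min()), int(common_years.max()))
    chrono_stats = ChronologyStats(ms=ms, rbar=rbar, eps=eps_val,
                                   common_period=common, n_series=len(indices))
    return Chronology(years=years, index=chron, sample_depth=depth,
                      component=indices[0].component, stats=chrono_stats)
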