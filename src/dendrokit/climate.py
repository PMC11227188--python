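"""Bootstrap correlation of a chronology with monthly climate.

Growth in year t is compared with monthly climate over a
"dendrochronological window" running from a month of the previous
calendar year (default June, written pJun) through a month of the
current year (default September), 16 months in the default window.
Significance comes from a case bootstrap over years: percentile
confidence intervals at 1 - alpha.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detrend import Chronology
from .rwl import ClimateTable, ClimateVariable

__all__ = [
    "DendroWindow",
    "ResponseResult",
    "align",
    "bootstrap_correlation",
    "write_response_csv",
]

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass(frozen=True)
class DendroWindow:
    """Month window (start in the previous year, end in the current year)."""

    start_month: int = 6   # June of year t-1
    end_month: int = 9     # September of year t

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12 or not 1 <= self.end_month <= 12:
            raise ValueError("months must be 1..12")

    def months(self) -> list[tuple[int, int]]:
        """Ordered (month, lag) pairs; lag -1 is the previous year."""
        out = [(m, -1) for m in range(self.start_month, 13)]
        out += [(m, 0) for m in range(1, self.end_month + 1)]
        return out

    def labels(self) -> list[str]:
        return [("p" if lag else "") + _MONTH_ABBR[m - 1] for m, lag in self.months()]

    def __len__(self) -> int:
        return len(self.months())


@dataclass
class ResponseResult:
    """Correlation of one climate month with the chronology."""

    variable: ClimateVariable
    month_label: str
    r: float
    ci_low: float
    ci_high: float
    significant: bool
    n_years: int
    n_boot: int
    seed: int | None = None


def align(
    chronology: Chronology,
    climate: ClimateTable,
    window: DendroWindow | None = None,
    min_overlap: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Build the year-aligned design matrix for one climate variable.

    Returns ``(years, y, X, labels)`` where ``y`` is the chronology index
    and ``X`` has one column per window month.  A response year is kept
    only when the chronology and every window month are non-missing;
    previous-year months are taken from calendar year t - 1.
    """
    window = window or DendroWindow()
    months = window.months()
    years, rows, y = [], [], []
    chron_index = dict(zip(chronology.years.tolist(), chronology.index.tolist()))
    for t, xt in chron_index.items():
        if not np.isfinite(xt):
            continue
        row = [climate.value(t + lag, m) for m, lag in months]
        if any(np.isnan(v) for v in row):
            continue
        years.append(t)
        y.append(xt)
        rows.append(row)
    if len(years) < min_overlap:
        raise ValueError(
            f"chronology/climate overlap too short: {len(years)} usable years "
            f"(need >= {min_overlap})"
        )
    order = np.argsort(years)
    return (np.array(years)[order], np.array(y)[order],
            np.array(rows)[order], window.labels())


def _pearson_columns(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of y against each column of x; NaN for zero variance.

    Supports a stacked ``y``/``x`` with a leading bootstrap axis.
    """
    yc = y - y.mean(axis=-1, keepdims=True)
    xc = x - x.mean(axis=-2, keepdims=True)
    cov = np.einsum("...n,...nm->...m", yc, xc)
    sy = np.sqrt(np.einsum("...n,...n->...", yc, yc))
    sx = np.sqrt(np.einsum("...nm,...nm->...m", xc, xc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sy[..., None] * sx)
    return r


def bootstrap_correlation(
    chronology: Chronology,
    climate: ClimateTable,
    window: DendroWindow | None = None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    bonferroni: bool = False,
    min_overlap: int = 30,
) -> list[ResponseResult]:
    """Monthly Pearson correlations with case-bootstrap percentile CIs.

    Years are resampled with replacement ``n_boot`` times; a month is
    significant when 0 lies outside its (alpha/2, 1-alpha/2) percentile
    interval.  Deterministic for a given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    window = window or DendroWindow()
    _, y, x, labels = align(chronology, climate, window, min_overlap=min_overlap)
    n = len(y)
    alpha_eff = alpha / len(labels) if bonferroni else alpha

    r_hat = _pearson_columns(y, x)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    r_boot = _pearson_columns(y[idx], x[idx])  # (n_boot, n_months)

    results = []
    for j, label in enumerate(labels):
        rj = float(r_hat[j])
        if not np.isfinite(rj):
            results.append(ResponseResult(
                variable=climate.variable, month_label=label, r=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), significant=False,
                n_years=n, n_boot=n_boot, seed=seed))
            continue
        col = r_boot[:, j]
        col = col[np.isfinite(col)]
        lo, hi = np.percentile(col, [100 * alpha_eff / 2, 100 * (1 - alpha_eff / 2)])
        significant = not (lo <= 0.0 <= hi)
        results.append(ResponseResult(
            variable=climate.variable, month_label=label, r=rj,
            ci_low=float(lo), ci_high=float(hi), significant=bool(significant),
            n_years=n, n_boot=n_boot, seed=seed))
    return results


def write_response_csv(results: Sequence[ResponseResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variable", "month", "r", "ci_low", "ci_high",
                         "significant", "n_years"])
        for res in results:
            writer.writerow([res.variable.value, res.month_label,
                             repr(res.r), repr(res.ci_low), repr(res.ci_high),
                             int(res.significant), res.n_years])
    return path
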