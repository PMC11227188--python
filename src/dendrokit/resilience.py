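"""Per-tree drought resistance/recovery/resilience and decline statistics.

For a year t and an index series x:

* resistance   Rt = x[t] / mean(x[t-pre .. t-1])
* recovery     Rc = mean(x[t+1 .. t+post]) / x[t]
* resilience   Rs = mean(x[t+1 .. t+post]) / D, where D is the pre-event
  mean (default, making Rs == Rt * Rc exactly) or x[t-1]

Per-event decline statistics use a flank mean (Pre5), the latest minimum
inside the event and the decline-phase length Dt:
DecU = (Pre5 - Min) / Dt.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .detrend import Chronology, IndexSeries

__all__ = [
    "DroughtCalendar",
    "RsDenominator",
    "ResilienceConfig",
    "ResilienceRecord",
    "DeclineRecord",
    "DensitySummary",
    "indices_at_year",
    "evaluate_all",
    "summarize_events",
    "detect_decline_phase",
    "low_growth_periods",
    "density_summary",
    "write_records_csv",
    "write_declines_csv",
]

logger = logging.getLogger(__name__)

#: severe historical drought events used throughout (inclusive year ranges)
DEFAULT_EVENTS: tuple[tuple[int, int], ...] = (
    (1750, 1755), (1785, 1786), (1808, 1811), (1819, 1823), (1894, 1899),
    (1909, 1910), (1951, 1957), (2011, 2012), (2020, 2022),
)


@dataclass(frozen=True)
class DroughtCalendar:
    """Sorted, non-overlapping inclusive year ranges of drought events."""

    events: tuple[tuple[int, int], ...] = DEFAULT_EVENTS

    def __post_init__(self) -> None:
        events = tuple((int(a), int(b)) for a, b in self.events)
        object.__setattr__(self, "events", events)
        prev_end = None
        for start, end in events:
            if start > end:
                raise ValueError(f"event {start}-{end}: start > end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("events must be sorted and non-overlapping")
            prev_end = end

    @classmethod
    def default(cls) -> "DroughtCalendar":
        return cls(DEFAULT_EVENTS)

    def contains(self, year: int) -> bool:
        return any(a <= year <= b for a, b in self.events)

    def event_of(self, year: int) -> tuple[int, int] | None:
        for a, b in self.events:
            if a <= year <= b:
                return (a, b)
        return None

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


class RsDenominator(str, Enum):
    PRE_MEAN = "PRE_MEAN"   # 2-yr pre-event mean; Rs == Rt * Rc
    LAG1 = "LAG1"           # x[t-1], as printed in the source formula


@dataclass(frozen=True)
class ResilienceConfig:
    pre_window: int = 2
    post_window: int = 2
    rs_denominator: RsDenominator = RsDenominator.PRE_MEAN
    flank: int = 5
    eval_range: tuple[int, int] = (1750, 2022)

    def __post_init__(self) -> None:
        if self.pre_window < 1 or self.post_window < 1 or self.flank < 1:
            raise ValueError("pre_window, post_window and flank must be >= 1")
        object.__setattr__(self, "rs_denominator", RsDenominator(self.rs_denominator))


@dataclass
class ResilienceRecord:
    tree_id: str
    year: int
    rt: float
    rc: float
    rs: float


@dataclass
class DeclineRecord:
    tree_id: str
    event: tuple[int, int]
    decline_start_year: int
    min_year: int
    min_value: float
    pre5: float
    dt: int
    dec_u: float
    negative_flagged: bool = False
    unit: str = "index"


@dataclass
class DensitySummary:
    indicator: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    skewness: float
    n: int


# ---------------------------------------------------------------------------

def indices_at_year(series: IndexSeries, t: int,
                    config: ResilienceConfig | None = None) -> tuple[float, float, float]:
    """(Rt, Rc, Rs) at year t; raises ValueError when ineligible."""
    config = config or ResilienceConfig()
    if t - config.pre_window < series.first_year or t + config.post_window > series.last_year:
        raise ValueError(f"year {t} window extends beyond series span")
    i = t - series.first_year
    x = series.indices
    pre = x[i - config.pre_window: i]
    post = x[i + 1: i + 1 + config.post_window]
    xt = x[i]
    pre_mean = float(np.mean(pre))
    post_mean = float(np.mean(post))
    if pre_mean <= 0:
        raise ValueError(f"year {t}: non-positive pre-event mean")
    if xt <= 0:
        raise ValueError(f"year {t}: non-positive index at event year")
    rt = xt / pre_mean
    rc = post_mean / xt
    if config.rs_denominator is RsDenominator.PRE_MEAN:
        rs = post_mean / pre_mean
    else:
        lag1 = x[i - 1]
        if lag1 <= 0:
            raise ValueError(f"year {t}: non-positive index at t-1")
        rs = post_mean / lag1
    return float(rt), float(rc), float(rs)


def evaluate_all(trees: Sequence[IndexSeries],
                 config: ResilienceConfig | None = None) -> list[ResilienceRecord]:
    """One record per tree per eligible year of the evaluation range.

    Ineligible years (window out of span, zero denominators) are skipped
    with a debug log.  Output ordered by (tree_id, year).
    """
    config = config or ResilienceConfig()
    if not trees:
        raise ValueError("no index series given")
    lo, hi = config.eval_range
    records: list[ResilienceRecord] = []
    for series in sorted(trees, key=lambda s: s.series_id):
        for t in range(lo, hi + 1):
            try:
                rt, rc, rs = indices_at_year(series, t, config)
            except ValueError as exc:
                logger.debug("skip %s @ %d: %s", series.series_id, t, exc)
                continue
            records.append(ResilienceRecord(series.series_id, t, rt, rc, rs))
    return records


def summarize_events(trees: Sequence[IndexSeries],
                     calendar: DroughtCalendar | None = None,
                     config: ResilienceConfig | None = None) -> list[ResilienceRecord]:
    """Per-tree, per-event indicators evaluated at the event's minimum-index year."""
    calendar = calendar or DroughtCalendar.default()
    config = config or ResilienceConfig()
    out: list[ResilienceRecord] = []
    for series in sorted(trees, key=lambda s: s.series_id):
        for start, end in calendar:
            years = [t for t in range(start, end + 1)
                     if series.first_year <= t <= series.last_year]
            if not years:
                continue
            vals = [series.value_at(t) for t in years]
            t_min = years[int(np.argmin(vals))]
            try:
                rt, rc, rs = indices_at_year(series, t_min, config)
            except ValueError:
                continue
            out.append(ResilienceRecord(series.series_id, t_min, rt, rc, rs))
    return out


# ---------------------------------------------------------------------------

def detect_decline_phase(
    series: IndexSeries,
    event: tuple[int, int],
    flank: int = 5,
    calendar: DroughtCalendar | None = None,
    floor_at_zero: bool = False,
) -> DeclineRecord:
    """Decline statistics for one tree over one drought event.

    ``min_year`` is the LATEST year attaining the event minimum; the
    decline phase runs from the event start to ``min_year``.  ``Pre5``
    pools both flanks (``flank`` years before the start and after the
    end); flank years inside another calendar event are dropped.
    """
    start, end = int(event[0]), int(event[1])
    if start > end:
        raise ValueError("event start after end")
    flank_years = list(range(start - flank, start)) + list(range(end + 1, end + flank + 1))
    missing = [y for y in flank_years + list(range(start, end + 1))
               if not series.first_year <= y <= series.last_year]
    if missing:
        raise ValueError(
            f"series {series.series_id!r}: years {missing} outside span "
            f"{series.first_year}-{series.last_year}"
        )
    if calendar is not None:
        kept = [y for y in flank_years
                if calendar.event_of(y) in (None, (start, end))]
        dropped = sorted(set(flank_years) - set(kept))
        if dropped:
            logger.info("series %s event %s: flank years %s inside other events dropped",
                        series.series_id, (start, end), dropped)
        flank_years = kept
    if not flank_years:
        raise ValueError("no flank years left after overlap exclusion")

    flank_vals = np.array([series.value_at(y) for y in flank_years])
    pre5 = float(np.mean(flank_vals))

    event_years = np.arange(start, end + 1)
    event_vals = np.array([series.value_at(y) for y in event_years])
    vmin = float(np.min(event_vals))
    min_year = int(event_years[np.flatnonzero(event_vals == vmin)[-1]])  # latest tie

    decline_start = start
    dt = min_year - decline_start + 1
    dec_u = (pre5 - vmin) / dt
    flagged = dec_u < 0
    if floor_at_zero and dec_u < 0:
        dec_u = 0.0
    return DeclineRecord(
        tree_id=series.series_id, event=(start, end),
        decline_start_year=decline_start, min_year=min_year,
        min_value=vmin, pre5=pre5, dt=dt, dec_u=float(dec_u),
        negative_flagged=bool(flagged),
    )


def low_growth_periods(chronology: Chronology, k: float = 1.0,
                       min_run: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive years below mean - k*SD."""
    if len(chronology) < 30:
        raise ValueError("chronology too short (< 30 years)")
    x = chronology.index
    threshold = float(np.mean(x)) - k * float(np.std(x, ddof=1))
    below = x < threshold
    years = chronology.years
    periods: list[tuple[int, int]] = []
    i, n = 0, len(below)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1] and years[j + 1] == years[j] + 1:
            j += 1
        if j - i + 1 >= min_run:
            periods.append((int(years[i]), int(years[j])))
        i = j + 1
    return periods


# ---------------------------------------------------------------------------

def density_summary(values: Sequence[float], indicator: str,
                    grid_size: int = 512) -> DensitySummary:
    """Gaussian KDE (Silverman bandwidth) plus adjusted Fisher-Pearson skewness."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError("need at least 5 values for a density summary")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bandwidth = float(kde.factor * np.std(x, ddof=1))
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, grid_size)
    density = kde(grid)
    skewness = float(stats.skew(x, bias=False))
    return DensitySummary(indicator=indicator, grid=grid, density=density,
                          bandwidth=bandwidth, skewness=skewness, n=int(x.size))


# ---------------------------------------------------------------------------

def write_records_csv(records: Sequence[ResilienceRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tree_id", "year", "Rt", "Rc", "Rs"])
        for rec in records:
            writer.writerow([rec.tree_id, rec.year, repr(rec.rt), repr(rec.rc), repr(rec.rs)])
    return path


def write_declines_csv(declines: Sequence[DeclineRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tree_id", "event_start", "event_end", "min_year",
                         "Pre5", "Min", "Dt", "DecU"])
        for d in declines:
            writer.writerow([d.tree_id, d.event[0], d.event[1], d.min_year,
                             repr(d.pre5), repr(d.min_value), d.dt, repr(d.dec_u)])
    return path
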