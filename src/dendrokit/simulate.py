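"""Synthetic forest and climate generation with known ground truth.

Per tree, annual growth is multiplicative:

    width_t = agecurve_t * exp(a_t) * m_t,   a_t = phi*a_{t-1} + beta*z_t + eps_t

where ``agecurve`` is a negative-exponential juvenile trend, ``a`` is a
lognormal AR(1) anomaly driven by a shared standardized climate signal
``z`` (growing-season precipitation) plus independent noise, and ``m``
is the drought multiplier: (1 - delta) inside calendar events, relaxing
linearly back to 1 over ``recovery_years`` afterwards.  The multiplier
acts on the level, not the log, so event-year resistance targets
(1 - delta) exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np

from .resilience import DroughtCalendar
from .rwl import (
    ClimateTable,
    ClimateVariable,
    RingWidthSeries,
    SeriesCollection,
    WoodComponent,
)

__all__ = ["SimulationConfig", "SyntheticForest", "simulate_climate",
           "simulate_forest", "drought_multipliers", "write_forest"]

# per-variable (annual mean, seasonal amplitude, noise SD, peak month)
_CLIMATE_SHAPE: dict[ClimateVariable, tuple[float, float, float, int]] = {
    ClimateVariable.Prec: (120.0, 80.0, 25.0, 7),
    ClimateVariable.EvT: (70.0, 25.0, 8.0, 5),
    ClimateVariable.Tmax: (24.0, 4.0, 1.0, 5),
    ClimateVariable.Tmin: (10.0, 4.0, 1.0, 7),
    ClimateVariable.PDSI: (0.0, 0.0, 2.0, 7),
    ClimateVariable.SPEI6: (0.0, 0.0, 1.0, 7),
}

#: drought-year monthly anomalies (additive unless noted)
_PREC_DROUGHT_FACTOR = 0.55   # multiplicative deficit on precipitation
_TMAX_DROUGHT_SURPLUS = 1.5   # degC
_INDEX_DROUGHT_SHIFT = {ClimateVariable.PDSI: -2.5, ClimateVariable.SPEI6: -1.2}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a synthetic forest."""

    n_trees: int = 15
    year_range: tuple[int, int] = (1700, 2022)
    age_initial: float = 2.0        # mm, juvenile growth level
    age_rate: float = 0.01          # 1/yr negative-exponential decay
    age_floor: float = 0.5          # mm, mature asymptote
    ar_phi: float = 0.3
    noise_sd: float = 0.2           # lognormal sigma of the tree-level noise
    climate_beta: float = 0.3       # log-growth response to the shared signal
    drought_calendar: DroughtCalendar = field(default_factory=DroughtCalendar.default)
    drought_delta: float = 0.4      # fractional growth reduction in event years
    recovery_years: int = 2         # linear relaxation lag after each event
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drought_delta < 1:
            raise ValueError("drought_delta must be in [0, 1)")
        if not 0 <= self.ar_phi <= 0.9:
            raise ValueError("ar_phi must be in [0, 0.9]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.recovery_years < 0:
            raise ValueError("recovery_years must be >= 0")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start after end")

    @property
    def n_years(self) -> int:
        return self.year_range[1] - self.year_range[0] + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


@dataclass
class SyntheticForest:
    collection: SeriesCollection
    climate: dict[ClimateVariable, ClimateTable]
    config: SimulationConfig
    multipliers: np.ndarray          # realized per-year drought multipliers
    climate_signal: np.ndarray       # standardized shared signal z_t

    @property
    def years(self) -> np.ndarray:
        return self.config.years


def drought_multipliers(years: np.ndarray, calendar: DroughtCalendar,
                        delta: float, recovery_years: int) -> np.ndarray:
    """Per-year level multipliers: 1-delta in events, linear relaxation after."""
    m = np.ones(len(years), dtype=float)
    year_pos = {int(y): i for i, y in enumerate(years)}
    for start, end in calendar:
        for y in range(start, end + 1):
            if y in year_pos:
                m[year_pos[y]] = min(m[year_pos[y]], 1.0 - delta)
        for j in range(1, recovery_years + 1):
            y = end + j
            if y in year_pos and not calendar.contains(y):
                relaxed = 1.0 - delta * (1.0 - j / (recovery_years + 1.0))
                m[year_pos[y]] = min(m[year_pos[y]], relaxed)
    return m


def simulate_climate(config: SimulationConfig,
                     seed: int | None = None) -> dict[ClimateVariable, ClimateTable]:
    """Monthly tables for all six variables, with drought-year anomalies."""
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(len(_CLIMATE_SHAPE))
    years = config.years
    n = len(years)
    drought = np.array([config.drought_calendar.contains(int(y)) for y in years])
    months = np.arange(12)
    out: dict[ClimateVariable, ClimateTable] = {}
    for (var, (mean, amp, sd, peak)), ss in zip(_CLIMATE_SHAPE.items(), streams):
        rng = np.random.default_rng(ss)
        seasonal = mean + amp * np.cos(2 * np.pi * (months - (peak - 1)) / 12.0)
        values = seasonal[None, :] + rng.normal(0.0, sd, size=(n, 12))
        if var is ClimateVariable.Prec:
            values = np.maximum(values, 0.0)
            values[drought] *= _PREC_DROUGHT_FACTOR
        elif var is ClimateVariable.EvT:
            values = np.maximum(values, 0.0)
        elif var is ClimateVariable.Tmax:
            values[drought] += _TMAX_DROUGHT_SURPLUS
        elif var in _INDEX_DROUGHT_SHIFT:
            values[drought] += _INDEX_DROUGHT_SHIFT[var]
        out[var] = ClimateTable(variable=var, first_year=int(years[0]), values=values)
    return out


def _growing_season_signal(prec: ClimateTable) -> np.ndarray:
    """Standardized June-September precipitation total per year."""
    total = np.nansum(prec.values[:, 5:9], axis=1)
    sd = total.std(ddof=1)
    if sd == 0:
        return np.zeros_like(total)
    return (total - total.mean()) / sd


def simulate_forest(config: SimulationConfig) -> SyntheticForest:
    """Generate a latewood-width collection plus matching climate tables."""
    climate = simulate_climate(config)
    z = _growing_season_signal(climate[ClimateVariable.Prec])
    years = config.years
    n = config.n_years
    ages = np.arange(n)
    agecurve = config.age_floor + config.age_initial * np.exp(-config.age_rate * ages)
    m = drought_multipliers(years, config.drought_calendar, config.drought_delta,
                            config.recovery_years)

    tree_streams = np.random.SeedSequence(config.seed).spawn(config.n_trees + 1)[1:]
    phi, beta, sigma = config.ar_phi, config.climate_beta, config.noise_sd
    series = []
    for k, ss in enumerate(tree_streams):
        rng = np.random.default_rng(ss)
        eps = rng.normal(0.0, sigma, size=n)
        a = np.empty(n)
        a[0] = beta * z[0] + (eps[0] / np.sqrt(1.0 - phi ** 2) if phi else eps[0])
        for t in range(1, n):
            a[t] = phi * a[t - 1] + beta * z[t] + eps[t]
        widths = np.maximum(agecurve * np.exp(a) * m, 0.01)
        series.append(RingWidthSeries(
            series_id=f"SIM{k + 1:03d}", first_year=int(years[0]),
            values=widths, component=WoodComponent.LATEWOOD))
    collection = SeriesCollection(series=series, site_id="SYNTH",
                                  species="synthetic", component=WoodComponent.LATEWOOD)
    return SyntheticForest(collection=collection, climate=climate, config=config,
                           multipliers=m, climate_signal=z)


def write_forest(forest: SyntheticForest, out_dir: str | Path) -> dict[str, Path]:
    """Write lw.rwl, six climate CSVs and truth.json; returns path map."""
    from .rwl import write_climate_csv, write_rwl

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["rwl"] = write_rwl(forest.collection, out_dir / "lw.rwl")
    for var, table in forest.climate.items():
        paths[var.value] = write_climate_csv(table, out_dir / f"{var.value.lower()}.csv")
    truth = {
        "config": {
            **{k: v for k, v in asdict(forest.config).items() if k != "drought_calendar"},
            "drought_calendar": list(map(list, forest.config.drought_calendar.events)),
        },
        "years": forest.years.tolist(),
        "multipliers": forest.multipliers.tolist(),
        "climate_signal": forest.climate_signal.tolist(),
    }
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
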