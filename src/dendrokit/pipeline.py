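"""End-to-end orchestration: simulate/read -> detrend -> stats -> climate -> resilience."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import detrend as dt
from . import resilience as rl
from .climate import DendroWindow, bootstrap_correlation, write_response_csv
from .rwl import (
    ClimateVariable,
    WoodComponent,
    read_climate_csv,
    read_rwl,
    write_chronology_csv,
)
from .simulate import SimulationConfig, simulate_forest, write_forest

__all__ = ["RunConfig", "run_all", "PipelineError", "load_run_config"]

logger = logging.getLogger(__name__)

STATS_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig:
    """Validated run configuration assembled from a YAML mapping."""

    def __init__(self, raw: Mapping[str, Any], base_dir: Path | None = None):
        self.raw = dict(raw)
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()
        self.seed: int = int(raw.get("seed", 0))
        self.output_dir = self._resolve(raw.get("output_dir", "out"))

        sim = raw.get("simulate")
        self.simulate: SimulationConfig | None = None
        if sim is not None:
            sim = dict(sim)
            calendar = sim.pop("drought_calendar", None)
            if calendar is not None:
                sim["drought_calendar"] = rl.DroughtCalendar(
                    tuple(tuple(e) for e in calendar))
            if "year_range" in sim:
                sim["year_range"] = tuple(sim["year_range"])
            sim.setdefault("seed", self.seed)
            self.simulate = SimulationConfig(**sim)

        paths = dict(raw.get("paths", {}))
        self.rwl_path = self._resolve(paths["rwl"]) if "rwl" in paths else None
        self.climate_dir = self._resolve(paths["climate_dir"]) if "climate_dir" in paths else None
        self.events = paths.get("events", "default")

        det = dict(raw.get("detrend", {}))
        self.min_depth = int(det.pop("min_depth", 1))
        self.prewhiten = bool(det.pop("prewhiten", True))
        det.pop("seed", None)
        self.detrend = dt.DetrendConfig(**det)

        res = dict(raw.get("resilience", {}))
        if "eval_range" in res:
            res["eval_range"] = tuple(res["eval_range"])
        self.resilience = rl.ResilienceConfig(**res)

        boot = dict(raw.get("bootstrap", {}))
        self.n_boot = int(boot.get("n_boot", 1000))
        self.alpha = float(boot.get("alpha", 0.05))
        self.bonferroni = bool(boot.get("bonferroni", False))

    def _resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def calendar(self) -> rl.DroughtCalendar:
        if self.events == "default":
            return rl.DroughtCalendar.default()
        events = []
        for line in Path(self._resolve(self.events)).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("start"):
                continue
            a, b = line.replace(",", " ").split()[:2]
            events.append((int(a), int(b)))
        return rl.DroughtCalendar(tuple(events))


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return RunConfig(raw, base_dir=path.parent)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle into the output dir.

    Artifacts: chronology.csv, stats.json, responses.csv, resilience.csv,
    declines.csv, density.json, run.log and a copy of the configuration.
    Deterministic for a fixed seed.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("dendrokit")
    root.addHandler(handler)
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        (out / "config_used.yaml").write_text(yaml.safe_dump(config.raw, sort_keys=True))
        artifacts["config"] = out / "config_used.yaml"

        # --- inputs
        collection, climate_tables = _stage("inputs")(_load_inputs)(config, out)

        # --- detrend
        @_stage("detrend")
        def _detrend():
            indices = [dt.standardize(s, config.detrend) for s in collection]
            chron = dt.build_chronology(indices, min_depth=config.min_depth,
                                        biweight_c=config.detrend.biweight_c)
            if config.prewhiten:
                white = [dt.prewhiten_ar(ix, config.detrend.ar_max_order) for ix in indices]
                chron_climate = dt.build_chronology(white, min_depth=config.min_depth,
                                                    biweight_c=config.detrend.biweight_c)
            else:
                chron_climate = chron
            return indices, chron, chron_climate

        indices, chron, chron_climate = _detrend()
        artifacts["chronology"] = write_chronology_csv(
            chron.years, chron.index, chron.sample_depth, out / "chronology.csv")

        # --- stats
        @_stage("stats")
        def _stats():
            s = chron.stats
            payload = {
                "schema_version": STATS_SCHEMA_VERSION,
                "component": chron.component.value,
                "n_series": s.n_series,
                "ms": s.ms,
                "rbar": s.rbar,
                "eps": s.eps,
                "common_period": list(s.common_period) if s.common_period else None,
                "span": [int(chron.years[0]), int(chron.years[-1])],
            }
            p = out / "stats.json"
            p.write_text(json.dumps(payload, indent=2))
            return p

        artifacts["stats"] = _stats()

        # --- climate correlations
        @_stage("climcorr")
        def _climcorr():
            results = []
            for var, table in climate_tables.items():
                results.extend(bootstrap_correlation(
                    chron_climate, table, DendroWindow(),
                    n_boot=config.n_boot, alpha=config.alpha,
                    seed=config.seed, bonferroni=config.bonferroni))
            return write_response_csv(results, out / "responses.csv")

        if climate_tables:
            artifacts["responses"] = _climcorr()

        # --- resilience
        @_stage("resilience")
        def _resilience():
            calendar = config.calendar()
            records = rl.evaluate_all(indices, config.resilience)
            event_records = rl.summarize_events(indices, calendar, config.resilience)
            declines = []
            for series in indices:
                for event in calendar:
                    try:
                        declines.append(rl.detect_decline_phase(
                            series, event, flank=config.resilience.flank,
                            calendar=calendar))
                    except ValueError as exc:
                        logger.debug("decline skip %s %s: %s", series.series_id, event, exc)
            density = {}
            samples = {
                "Rt": [r.rt for r in records], "Rc": [r.rc for r in records],
                "Rs": [r.rs for r in records], "DecU": [d.dec_u for d in declines],
            }
            for name, sample in samples.items():
                if len(sample) >= 5 and np.ptp(sample) > 0:
                    summary = rl.density_summary(sample, name)
                    density[name] = {"skewness": summary.skewness,
                                     "bandwidth": summary.bandwidth,
                                     "n": summary.n,
                                     "mean": float(np.mean(sample)),
                                     "min": float(np.min(sample)),
                                     "max": float(np.max(sample))}
            a = {}
            a["resilience"] = rl.write_records_csv(records, out / "resilience.csv")
            a["event_summary"] = rl.write_records_csv(event_records, out / "event_summary.csv")
            a["declines"] = rl.write_declines_csv(declines, out / "declines.csv")
            (out / "density.json").write_text(json.dumps(density, indent=2))
            a["density"] = out / "density.json"
            return a

        artifacts.update(_resilience())
        return artifacts
    finally:
        root.removeHandler(handler)
        handler.close()


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        forest = simulate_forest(config.simulate)
        write_forest(forest, out / "inputs")
        return forest.collection, forest.climate
    if config.rwl_path is None:
        raise ValueError("config must provide either a 'simulate' block or paths.rwl")
    if not config.rwl_path.exists():
        raise FileNotFoundError(f"ring-width file not found: {config.rwl_path}")
    collection = read_rwl(config.rwl_path, component=WoodComponent.LATEWOOD)
    climate_tables = {}
    if config.climate_dir is not None:
        if not config.climate_dir.is_dir():
            raise FileNotFoundError(f"climate directory not found: {config.climate_dir}")
        for var in ClimateVariable:
            path = config.climate_dir / f"{var.value.lower()}.csv"
            if path.exists():
                climate_tables[var] = read_climate_csv(path, var)
    return collection, climate_tables
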