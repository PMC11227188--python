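import numpy as np
import pytest

from dendrokit import (
    DetrendConfig,
    DroughtCalendar,
    RingWidthSeries,
    SeriesCollection,
    SimulationConfig,
    simulate_forest,
    standardize,
)
from dendrokit.detrend import IndexSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_collection():
    """Three overlapping positive series, no missing rings."""
    gen = np.random.default_rng(7)
    series = []
    for k, (first, n) in enumerate([(1900, 100), (1910, 95), (1920, 80)]):
        vals = 1.5 + 0.4 * gen.standard_normal(n).cumsum() * 0.01 + 0.2 * gen.random(n)
        series.append(RingWidthSeries(f"TR{k + 1:02d}", first, np.abs(vals) + 0.1))
    return SeriesCollection(series=series)


@pytest.fixture
def default_forest():
    return simulate_forest(SimulationConfig(n_trees=8, year_range=(1740, 2022), seed=5))


@pytest.fixture
def forest_indices(default_forest):
    return [standardize(s, DetrendConfig()) for s in default_forest.collection]


def flat_index_series(series_id="FLAT", first_year=1700, n=330, value=1.0):
    return IndexSeries(series_id, first_year, np.full(n, float(value)))
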