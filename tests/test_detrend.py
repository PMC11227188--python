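import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from dendrokit.detrend import (
    Chronology,
    DetrendConfig,
    IndexSeries,
    biweight_mean,
    build_chronology,
    eps,
    fit_frequency_cutoff_spline,
    interseries_rbar,
    mean_sensitivity,
    prewhiten_ar,
    standardize,
)
from dendrokit.rwl import RingWidthSeries


def fitted_sine_amplitude(curve, period, edge):
    """Least-squares sinusoid amplitude on the interior of a fitted curve."""
    n = len(curve)
    t = np.arange(n)
    core = slice(edge, n - edge)
    design = np.c_[np.sin(2 * np.pi * t / period), np.cos(2 * np.pi * t / period),
                   np.ones(n)]
    coef, *_ = np.linalg.lstsq(design[core], curve[core], rcond=None)
    return float(np.hypot(coef[0], coef[1]))


class TestFrequencyCutoffSpline:
    def test_constant_input_reproduced(self):
        c = np.full(50, 3.7)
        np.testing.assert_allclose(fit_frequency_cutoff_spline(c, 30), c, atol=1e-10)

    def test_attenuation_at_cutoff_wavelength(self):
        # spectral oracle: sinusoid at period == wavelength is halved
        wl, n, amp = 30, 12 * 30, 2.0
        y = amp * np.sin(2 * np.pi * np.arange(n) / wl)
        fitted = fit_frequency_cutoff_spline(y, wl, 0.5)
        a = fitted_sine_amplitude(fitted, wl, edge=wl // 2)
        assert a == pytest.approx(0.5 * amp, rel=0.10)

    def test_low_frequency_passthrough(self):
        wl, n, amp = 30, 12 * 30, 1.0
        period = 10 * wl
        y = amp * np.sin(2 * np.pi * np.arange(n) / period)
        fitted = fit_frequency_cutoff_spline(y, wl, 0.5)
        a = fitted_sine_amplitude(fitted, period, edge=wl // 2)
        assert a >= 0.95 * amp

    def test_response_monotone_in_frequency(self):
        # frequency sweep: shorter periods must be attenuated more
        wl, n = 30, 1500
        t = np.arange(n)
        amps = []
        for period in [300, 120, 60, 30, 15, 8]:
            y = np.sin(2 * np.pi * t / period)
            fitted = fit_frequency_cutoff_spline(y, wl, 0.5)
            amps.append(fitted_sine_amplitude(fitted, period, edge=2 * wl))
        assert all(a >= b - 1e-6 for a, b in zip(amps, amps[1:]))

    def test_cutoff_response_parameter_respected(self):
        wl, n = 20, 1000
        y = np.sin(2 * np.pi * np.arange(n) / wl)
        for f in [0.25, 0.5, 0.75]:
            fitted = fit_frequency_cutoff_spline(y, wl, f)
            assert fitted_sine_amplitude(fitted, wl, edge=wl) == pytest.approx(f, rel=0.10)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fit_frequency_cutoff_spline([1.0, 2.0, 3.0], 30)


class TestStandardize:
    def test_flat_series_all_ones(self):
        s = RingWidthSeries("A", 1900, np.ones(5))
        idx = standardize(s)
        np.testing.assert_allclose(idx.indices, np.ones(5), atol=1e-10)

    def test_missing_ring_gives_zero_index(self):
        vals = np.ones(60)
        vals[30] = 0.0
        idx = standardize(RingWidthSeries("A", 1900, vals))
        assert idx.indices[30] == 0.0
        assert np.all(np.isfinite(idx.indices))
        assert np.all(idx.indices[np.arange(60) != 30] > 0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all rings are zero"):
            standardize(RingWidthSeries("A", 1900, np.zeros(10)))

    def test_difference_mode(self):
        s = RingWidthSeries("A", 1900, np.ones(10) * 2.0)
        idx = standardize(s, DetrendConfig(index_mode="DIFFERENCE"))
        np.testing.assert_allclose(idx.indices, np.zeros(10), atol=1e-10)

    def test_ratio_mean_near_one(self, rng):
        # stationary positive input -> RATIO chronology mean within 0.05 of 1
        series = [RingWidthSeries(f"S{k:02d}", 1800,
                                  np.exp(rng.normal(0, 0.2, 250)))
                  for k in range(10)]
        chron = build_chronology([standardize(s) for s in series])
        assert abs(chron.index.mean() - 1.0) < 0.05


class TestPrewhiten:
    def test_constant_returned_unchanged(self):
        s = IndexSeries("A", 1900, np.ones(100))
        out = prewhiten_ar(s, 3)
        assert out is s

    def test_white_noise_mostly_order_zero(self):
        # plain AIC keeps ~75% of white-noise series at order 0 (see ledger)
        gen = np.random.default_rng(42)
        kept = 0
        for _ in range(200):
            s = IndexSeries("A", 1800, gen.normal(1, 0.1, 200))
            if prewhiten_ar(s, 3).first_year == 1800:
                kept += 1
        assert 0.65 <= kept / 200 <= 0.95

    def test_ar1_residual_autocorrelation_small(self):
        gen = np.random.default_rng(1)
        worst = 0.0
        for _ in range(10):
            e = gen.normal(0, 0.1, 300)
            x = np.empty(300)
            x[0] = e[0]
            for t in range(1, 300):
                x[t] = 0.7 * x[t - 1] + e[t]
            out = prewhiten_ar(IndexSeries("A", 1700, x + 1.0), 3)
            r = out.indices - out.indices.mean()
            rho1 = np.corrcoef(r[:-1], r[1:])[0, 1]
            worst = max(worst, abs(rho1))
        assert worst < 0.1

    def test_residual_mean_is_one(self):
        gen = np.random.default_rng(3)
        x = np.empty(200)
        e = gen.normal(0, 0.1, 200)
        x[0] = e[0]
        for t in range(1, 200):
            x[t] = 0.6 * x[t - 1] + e[t]
        out = prewhiten_ar(IndexSeries("A", 1800, x + 1.0), 3)
        assert out.indices.mean() == pytest.approx(1.0, abs=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            prewhiten_ar(IndexSeries("A", 1900, np.random.default_rng(0).normal(1, 0.1, 12)), 3)


def biweight_oracle(x, c=9.0):
    """Independent route: minimize the biweight rho objective on a bracket."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return med

    def rho_sum(t):
        u = (x - t) / (c * mad)
        rho = np.where(np.abs(u) < 1, 1.0 - (1.0 - u ** 2) ** 3, 1.0)
        return float(np.sum(rho))

    res = optimize.minimize_scalar(rho_sum, bounds=(med - 3 * mad, med + 3 * mad),
                                   method="bounded", options={"xatol": 1e-10})
    return float(res.x)


class TestBiweightMean:
    def test_all_equal(self):
        assert biweight_mean([4.2, 4.2, 4.2, 4.2]) == 4.2

    def test_symmetric_triplet(self):
        assert biweight_mean([0.8, 1.0, 1.2]) == pytest.approx(1.0, abs=1e-9)

    def test_outlier_ignored(self):
        assert biweight_mean([1, 1, 1, 1, 100]) == pytest.approx(1.0, abs=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            biweight_mean([])

    def test_n_two_is_mean(self):
        assert biweight_mean([1.0, 3.0]) == 2.0

    def test_matches_root_finding_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(1, 0.2, n)
            x[: max(1, n // 10)] += rng.choice([-5, 5]) * rng.random()
            assert biweight_mean(x) == pytest.approx(biweight_oracle(x), abs=1e-6)

    def test_near_mean_on_clean_symmetric_samples(self, rng):
        for _ in range(20):
            half = rng.random(25)
            x = 1.0 + np.concatenate([half, -half])  # exactly symmetric
            assert biweight_mean(x) == pytest.approx(x.mean(), abs=1e-9)


class TestMeanSensitivity:
    def test_constant_zero(self):
        assert mean_sensitivity([2.0] * 10) == 0.0

    def test_hand_pair(self):
        assert mean_sensitivity([1, 2]) == pytest.approx(2 / 3)

    def test_hand_alternating(self):
        assert mean_sensitivity([1, 3, 1, 3]) == pytest.approx(1.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            mean_sensitivity([1.0])

    def test_zero_sum_pairs_skipped(self):
        assert np.isfinite(mean_sensitivity([1.0, 0.0, 0.0, 1.0]))

    @settings(max_examples=200, deadline=None)
    @given(
        values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=50),
        k=st.floats(0.001, 1000.0),
    )
    def test_scale_invariance(self, values, k):
        x = np.array(values)
        assert mean_sensitivity(k * x) == pytest.approx(mean_sensitivity(x), rel=1e-9)


class TestInterseriesRbar:
    def test_identical_series(self, rng):
        x = rng.normal(1, 0.2, 50)
        a = IndexSeries("A", 1900, x)
        b = IndexSeries("B", 1900, x.copy())
        assert interseries_rbar([a, b]) == pytest.approx(1.0)

    def test_negated_series(self, rng):
        x = rng.normal(0, 1, 50)
        a = IndexSeries("A", 1900, x)
        b = IndexSeries("B", 1900, -x)
        assert interseries_rbar([a, b]) == pytest.approx(-1.0)

    def test_constructed_pairwise_correlations(self):
        # brute-force oracle: build exact sample correlations via Cholesky
        target = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        n = 40
        gen = np.random.default_rng(0)
        raw = gen.normal(size=(n, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)  # orthonormal zero-mean-ish columns
        q -= q.mean(axis=0)
        q /= np.linalg.norm(q, axis=0)
        data = q @ np.linalg.cholesky(target).T
        series = [IndexSeries(f"S{j}", 1900, data[:, j]) for j in range(3)]
        # verify the construction with an independent pairwise loop
        got = []
        for i in range(3):
            for j in range(i + 1, 3):
                got.append(np.corrcoef(data[:, i], data[:, j])[0, 1])
        np.testing.assert_allclose(sorted(got), [0.2, 0.4, 0.6], atol=1e-8)
        assert interseries_rbar(series) == pytest.approx(0.4, abs=1e-8)

    def test_short_overlap_excluded(self, rng):
        a = IndexSeries("A", 1900, rng.normal(1, 0.1, 30))
        b = IndexSeries("B", 1925, rng.normal(1, 0.1, 30))  # 5-yr overlap
        with pytest.raises(ValueError, match="overlap"):
            interseries_rbar([a, b])

    def test_single_series_errors(self):
        with pytest.raises(ValueError):
            interseries_rbar([IndexSeries("A", 1900, np.ones(30))])


class TestEps:
    def test_perfect_rbar(self):
        for n in [1, 5, 50]:
            assert eps(1.0, n) == 1.0

    def test_zero_rbar(self):
        for n in [1, 5, 50]:
            assert eps(0.0, n) == 0.0

    def test_hand_value(self):
        assert eps(0.45, 15) == pytest.approx(6.75 / 7.30)

    def test_monotone_in_n_and_rbar(self):
        grid_r = np.linspace(0.05, 0.95, 10)
        grid_n = range(1, 40)
        for r in grid_r:
            vals = [eps(r, n) for n in grid_n]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        for n in grid_n:
            vals = [eps(r, n) for r in grid_r]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_limit_in_n(self):
        assert eps(0.1, 10_000_000) == pytest.approx(1.0, abs=1e-5)

    def test_strongly_negative_rbar_warns_zero(self):
        with pytest.warns(UserWarning):
            assert eps(-0.9, 3) == 0.0  # denominator -2.7 + 1.9 < 0


class TestBuildChronology:
    def test_single_series_identity(self, rng):
        x = rng.normal(1, 0.1, 60)
        chron = build_chronology([IndexSeries("A", 1900, x)])
        np.testing.assert_allclose(chron.index, x)
        assert np.all(chron.sample_depth == 1)

    def test_two_identical_series(self, rng):
        x = rng.normal(1, 0.1, 60)
        chron = build_chronology([IndexSeries("A", 1900, x),
                                  IndexSeries("B", 1900, x.copy())])
        np.testing.assert_allclose(chron.index, x)
        assert np.all(chron.sample_depth == 2)

    def test_staggered_sample_depth(self, rng):
        a = IndexSeries("A", 1900, rng.normal(1, 0.1, 40))   # 1900-1939
        b = IndexSeries("B", 1920, rng.normal(1, 0.1, 40))   # 1920-1959
        chron = build_chronology([a, b])
        assert list(chron.years) == list(range(1900, 1960))
        depth = dict(zip(chron.years.tolist(), chron.sample_depth.tolist()))
        assert depth[1910] == 1 and depth[1930] == 2 and depth[1950] == 1
        assert chron.stats.common_period == (1920, 1939)

    def test_min_depth_filters_years(self, rng):
        a = IndexSeries("A", 1900, rng.normal(1, 0.1, 40))
        b = IndexSeries("B", 1920, rng.normal(1, 0.1, 40))
        chron = build_chronology([a, b], min_depth=2)
        assert list(chron.years) == list(range(1920, 1940))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_chronology([])
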