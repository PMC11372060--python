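import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyanorhythm import (
    DomainError,
    FeatureError,
    PeakParams,
    StrainFirstPeak,
    find_peaks,
    find_troughs,
    first_cycle_period,
    first_peak_features,
    first_period_stats,
    phase_shift,
    relative_amplitude,
    summarize_strain,
)
from _oracles import brute_find_peaks


def loose(distance=1, height=None, width=None):
    return PeakParams(min_distance=distance, min_height=height, min_width=width)


class TestFindPeaks:
    def test_two_peaks(self):
        peaks = find_peaks([0, 3, 0, 5, 0], loose(distance=1, height=1))
        np.testing.assert_array_equal(peaks.indices, [1, 3])
        np.testing.assert_array_equal(peaks.heights, [3, 5])

    def test_distance_keeps_highest(self):
        peaks = find_peaks([0, 3, 0, 5, 0], loose(distance=3, height=1))
        np.testing.assert_array_equal(peaks.indices, [3])

    def test_plateau_midpoint(self):
        peaks = find_peaks([0, 2, 2, 0], loose())
        np.testing.assert_array_equal(peaks.indices, [1])

    def test_empty_result_allowed(self):
        assert len(find_peaks([0, 1, 2, 3, 4], loose())) == 0

    def test_matches_brute_force_on_random_signals(self, rng):
        """Implementation agrees with the exhaustive enumerator on random
        signals with random height/distance/width filters."""
        for _ in range(150):
            n = int(rng.integers(5, 61))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.5:
                x = np.cumsum(x)  # smoother signals with broad peaks
            distance = int(rng.integers(1, 11))
            height = float(rng.choice([-10.0, np.quantile(x, 0.5), np.quantile(x, 0.8)]))
            width = None if rng.random() < 0.5 else float(rng.integers(1, 7))
            got = find_peaks(x, loose(distance, height, width)).indices
            expected = brute_find_peaks(x, distance, height, width)
            np.testing.assert_array_equal(got, np.asarray(expected, dtype=int))

    def test_distance_rescaled_by_grid(self):
        p = PeakParams(min_distance=150, min_height=None, min_width=65.0)
        assert p.scaled_distance(1.0 / 12.0) == 150
        assert p.scaled_distance(1.0 / 6.0) == 75  # 10-min sampling
        assert p.scaled_width(1.0 / 6.0) == pytest.approx(32.5)


class TestFindTroughs:
    def test_single_trough_with_original_height(self):
        troughs = find_troughs([0, -3, 0], loose(height=1))
        np.testing.assert_array_equal(troughs.indices, [1])
        np.testing.assert_array_equal(troughs.heights, [-3])

    def test_cosine_troughs_at_odd_half_periods(self, grid_5min):
        y = 80.0 * np.cos(2 * np.pi * grid_5min / 24.0)
        troughs = find_troughs(y, PeakParams(min_distance=150, min_height=50.0), times=grid_5min)
        np.testing.assert_allclose(troughs.times, [12.0, 36.0, 60.0], atol=1.0 / 12.0)

    def test_monotone_ramp_has_no_troughs(self):
        assert len(find_troughs(np.linspace(0, 10, 50), loose())) == 0


class TestFirstCyclePeriod:
    def test_damped_cosine_closed_loop(self, grid_5min):
        """Trough-to-peak distance of a damped cosine is half the period
        regardless of the damping rate."""
        y = 60.0 * np.exp(-0.02 * grid_5min) * np.cos(2 * np.pi * grid_5min / 24.0 + 2.5)
        p = first_cycle_period(y, grid_5min, PeakParams(min_distance=150, min_height=10.0))
        assert p == pytest.approx(24.0, abs=2.0 / 12.0)

    def test_synthetic_trough_then_peak(self):
        t = np.arange(0, 40, 1.0 / 12.0)
        y = np.zeros_like(t)
        y[(t > 9) & (t < 11)] = -60.0  # trough around 10 h
        y[(t > 22) & (t < 24)] = 60.0  # peak around 23 h
        # round the plateaus so extrema are well defined
        y = np.convolve(y, np.ones(10) / 10, mode="same")
        p = first_cycle_period(y, t, PeakParams(min_distance=24, min_height=20.0))
        assert p == pytest.approx(26.0, abs=0.5)

    def test_flat_signal_raises(self, grid_5min):
        with pytest.raises(FeatureError):
            first_cycle_period(np.zeros_like(grid_5min), grid_5min)


class TestFirstPeakFeatures:
    def test_single_broad_peak(self, grid_5min):
        y = 90.0 * np.exp(-((grid_5min - 25.0) ** 2) / (2 * 6.0**2))
        t, h = first_peak_features(y, grid_5min)
        assert t == pytest.approx(25.0, abs=1.0 / 12.0)
        assert h == pytest.approx(90.0, rel=1e-6)

    def test_narrow_spike_filtered_by_width(self, grid_5min):
        broad = 90.0 * np.exp(-((grid_5min - 25.0) ** 2) / (2 * 6.0**2))
        spike = 120.0 * np.exp(-((grid_5min - 8.0) ** 2) / (2 * 0.3**2))
        t, h = first_peak_features(broad + spike, grid_5min)
        assert t == pytest.approx(25.0, abs=0.2)

    def test_below_threshold_everywhere(self, grid_5min):
        with pytest.raises(FeatureError):
            first_peak_features(
                np.full_like(grid_5min, 1.0),
                grid_5min,
                PeakParams(min_distance=150, min_height=50.0, min_width=65.0),
            )


class TestStrainSummaries:
    def test_mean_and_sd(self):
        s = summarize_strain("WT", [21.0, 22.0, 23.0], [10.0, 10.0, 10.0])
        assert s.peak_time_mean == 22.0
        assert s.peak_time_sd == pytest.approx(1.0)

    def test_single_well_sd_zero(self):
        s = summarize_strain("WT", [21.0], [55.0])
        assert s.peak_time_sd == 0.0 and s.peak_height_sd == 0.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(20, 3, 7)
        h = rng.normal(60, 5, 7)
        s = summarize_strain("WT", x, h)
        n = len(x)
        assert s.peak_time_mean == pytest.approx(sum(x) / n, abs=1e-12)
        var = sum((v - sum(x) / n) ** 2 for v in x) / (n - 1)
        assert s.peak_time_sd == pytest.approx(var**0.5, abs=1e-12)


def sfp(strain, t_mean, t_sd, h_mean, h_sd, n=5):
    return StrainFirstPeak(
        strain=strain, n_wells=n, peak_time_mean=t_mean, peak_time_sd=t_sd,
        peak_height_mean=h_mean, peak_height_sd=h_sd,
    )


class TestComparisons:
    def test_phase_shift_values(self):
        shift, err = phase_shift(sfp("m", 21.0, 0.5, 30.0, 3.0), sfp("wt", 28.0, 0.4, 90.0, 9.0))
        assert shift == pytest.approx(-7.0)
        assert err == pytest.approx(0.9)

    def test_phase_shift_self_is_zero(self):
        s = sfp("wt", 22.0, 0.5, 80.0, 4.0)
        assert phase_shift(s, s)[0] == 0.0

    def test_relative_amplitude_values(self):
        ratio, err = relative_amplitude(sfp("m", 21.0, 0.5, 30.0, 3.0), sfp("wt", 28.0, 0.4, 90.0, 9.0))
        assert ratio == pytest.approx(1.0 / 3.0)
        assert err == pytest.approx(0.2)  # 3/30 + 9/90

    def test_relative_amplitude_self_is_one(self):
        s = sfp("wt", 22.0, 0.5, 80.0, 4.0)
        assert relative_amplitude(s, s)[0] == pytest.approx(1.0)

    def test_zero_reference_height_rejected(self):
        with pytest.raises(DomainError):
            relative_amplitude(sfp("m", 21, 0.5, 30, 3), sfp("wt", 28, 0.4, 0.0, 0.0))

    @given(
        st.floats(10, 40), st.floats(0, 2), st.floats(1, 100), st.floats(0, 10),
        st.floats(10, 40), st.floats(0, 2), st.floats(1, 100), st.floats(0, 10),
    )
    def test_antisymmetry_and_reciprocity(self, t1, s1, h1, e1, t2, s2, h2, e2):
        a, b = sfp("a", t1, s1, h1, e1), sfp("b", t2, s2, h2, e2)
        assert phase_shift(a, b)[0] == pytest.approx(-phase_shift(b, a)[0], abs=1e-9)
        r_ab, err_ab = relative_amplitude(a, b)
        r_ba, err_ba = relative_amplitude(b, a)
        assert r_ab * r_ba == pytest.approx(1.0, rel=1e-9)
        assert err_ab >= 0 and err_ba >= 0
        assert phase_shift(a, b)[1] >= 0


class TestFirstPeriodStats:
    def test_summary_values(self, grid_5min):
        signals = [
            60.0 * np.cos(2 * np.pi * grid_5min / p + 2.5)
            for p in (20.0, 22.0, 24.0)
        ]
        stats = first_period_stats(
            "WT", signals, grid_5min, PeakParams(min_distance=100, min_height=30.0)
        )
        assert stats.mean == pytest.approx(22.0, abs=0.2)
        assert stats.median == pytest.approx(22.0, abs=0.2)

    def test_single_well_sd_zero(self, grid_5min):
        y = [60.0 * np.cos(2 * np.pi * grid_5min / 24.0 + 2.5)]
        stats = first_period_stats("WT", y, grid_5min, PeakParams(min_distance=150, min_height=30.0))
        assert stats.sd == 0.0

    def test_all_wells_failing_raises(self, grid_5min):
        with pytest.raises(FeatureError):
            first_period_stats("WT", [np.zeros_like(grid_5min)], grid_5min)
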