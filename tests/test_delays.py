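import numpy as np
import pytest

from nldfc import (Coupling, SimulationSpec, average_event_delay, delay_matrix,
                   detect_events, event_delay, find_target_peak, gen_coupled,
                   lagged_crosscov, parabolic_vertex, pearson_delay, zscore,
                   RoiTimeSeries)


def _zscore_pop(x):
    return (x - x.mean()) / x.std()


class TestLaggedCrosscov:
    def test_zero_lag_autocovariance_is_one(self, rng):
        x = _zscore_pop(rng.standard_normal(60))
        cov = lagged_crosscov(x, x, 5)
        assert cov.at(0) == pytest.approx(1.0, abs=1e-12)

    def test_shifted_copy_extremum_at_minus_shift(self, rng):
        base = np.convolve(rng.standard_normal(80), np.ones(5) / 5, "same")
        x_i = _zscore_pop(base[2:-2])
        x_j = _zscore_pop(base[:-4])        # x_j(t) = x_i(t - 2)
        cov = lagged_crosscov(x_i, x_j, 6)
        assert cov.lags[np.argmax(cov.values)] == -2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(20, 51))
        L = int(rng.integers(2, T // 2))
        x_i = rng.standard_normal(T)
        x_j = rng.standard_normal(T)
        cov = lagged_crosscov(x_i, x_j, L)
        for tau in range(-L, L + 1):
            if tau >= 0:
                expected = sum(x_i[t + tau] * x_j[t]
                               for t in range(T - tau)) / T
            else:
                expected = sum(x_j[t - tau] * x_i[t]
                               for t in range(T + tau)) / T
            assert cov.at(tau) == pytest.approx(expected, abs=1e-12), tau

    def test_reversal_identity_exact(self, rng):
        x, y = rng.standard_normal((2, 50))
        c_xy = lagged_crosscov(x, y, 8)
        c_yx = lagged_crosscov(y, x, 8)
        np.testing.assert_array_equal(c_xy.values, c_yx.values[::-1])

    def test_excessive_lag_rejected(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError):
            lagged_crosscov(x, x, 10)


class TestParabolicVertex:
    def test_symmetric_peak_centered(self):
        assert parabolic_vertex(0.5, 1.0, 0.5) == 0.0

    def test_known_parabola_third(self):
        # parabola through (-1,0),(0,1),(1,0.8) has vertex at x = 1/3
        assert parabolic_vertex(0.0, 1.0, 0.8) == pytest.approx(1 / 3,
                                                                abs=1e-12)

    def test_degenerate_denominator_gives_zero(self):
        assert parabolic_vertex(1.0, 1.0, 1.0) == 0.0

    def test_offset_clamped_to_unit_interval(self):
        assert abs(parabolic_vertex(0.0, 1.0, 0.999999)) <= 1.0

    def test_works_for_minima(self):
        # symmetric trough: vertex at centre
        assert parabolic_vertex(-0.5, -1.0, -0.5) == 0.0


class TestPearsonDelay:
    def test_self_delay_zero(self, rng):
        x = _zscore_pop(np.convolve(rng.standard_normal(100),
                                    np.ones(4) / 4, "same"))
        assert pearson_delay(x, x, 8) == 0.0

    def test_shift_sign_swaps_under_argument_exchange(self, rng):
        base = np.convolve(rng.standard_normal(120), np.ones(6) / 6, "same")
        x_i = _zscore_pop(base[3:-3])
        x_j = _zscore_pop(base[:-6])        # x_j delayed copy, 3 samples
        tau_ij = pearson_delay(x_i, x_j, 8)
        tau_ji = pearson_delay(x_j, x_i, 8)
        assert tau_ij == pytest.approx(-3.0, abs=0.25)
        assert tau_ji == pytest.approx(-tau_ij, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetry_exact_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 90))
        assert pearson_delay(x, y, 10) == pytest.approx(
            -pearson_delay(y, x, 10), abs=1e-12)

    def test_anticorrelated_propagation_captured(self, rng):
        base = np.convolve(rng.standard_normal(120), np.ones(6) / 6, "same")
        x_i = _zscore_pop(base[2:-2])
        x_j = _zscore_pop(-base[:-4])
        tau = pearson_delay(x_i, x_j, 8)
        assert tau == pytest.approx(-2.0, abs=0.5)


class TestFindTargetPeak:
    def test_clean_bump_located(self):
        x = np.zeros(40)
        x[22] = 1.0
        x[21] = x[23] = 0.5
        res = find_target_peak(x, 20)
        assert res.index == 22 and res.edge is None

    def test_equidistant_tie_goes_to_earlier_peak(self):
        x = np.zeros(40)
        x[17] = x[23] = 1.0
        x[16] = x[18] = x[22] = x[24] = 0.4
        res = find_target_peak(x, 20)
        assert res.index == 17

    def test_monotone_segment_flags_right_edge(self):
        x = np.linspace(0, 5, 40)
        res = find_target_peak(x, 20)
        assert res.edge == "right"
        assert res.index == 28

    def test_negative_polarity_finds_trough(self):
        x = np.zeros(40)
        x[22] = -2.0
        x[21] = x[23] = -1.0
        res = find_target_peak(x, 20, polarity="negative")
        assert res.index == 22

    def test_low_prominence_ripple_ignored(self):
        x = np.zeros(40)
        x[19] = 0.05                      # tiny ripple near the reference
        x[25] = 2.0
        x[24] = x[26] = 1.0
        res = find_target_peak(x, 20)
        assert res.index == 25
        res0 = find_target_peak(x, 20, min_prominence=0.0)
        assert res0.index == 19

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            find_target_peak(np.zeros(5), 20)


class TestEventDelay:
    def test_series_against_itself_all_zero(self, coupled_series):
        series, _ = coupled_series
        ev = detect_events(series, "r0")
        res = event_delay(series.column("r0"), series.column("r0"),
                          ev.crossing_times)
        np.testing.assert_allclose(res.per_event, 0.0, atol=1e-12)

    def test_integer_shift_recovered_noiseless(self):
        spec = SimulationSpec(n_regions=2, n_timepoints=300, noise_scale=0.0,
                              couplings=(Coupling("r0", "r1", lag_tr=2.0),),
                              seed=3)
        series, _ = gen_coupled(spec)
        ev = detect_events(series, "r0")
        res = event_delay(series.column("r0"), series.column("r1"),
                          ev.crossing_times)
        assert res.mean == pytest.approx(2.0, abs=0.25)

    def test_subsample_lag_recovered_single_seed(self, coupled_series):
        series, truth = coupled_series
        ev = detect_events(series, "r0")
        res = event_delay(series.column("r0"), series.column("r1"),
                          ev.crossing_times)
        assert res.mean == pytest.approx(truth.lags[("r0", "r1")], abs=0.5)

    def test_edge_peak_clamped_to_plus_six(self):
        # target rises monotonically across every search window
        T = 60
        x_i = np.zeros(T)
        x_i[28:31] = (1.5, 3.0, 1.5)
        x_j = np.linspace(0, 6, T)
        res = event_delay(_zscore_pop(x_i), x_j, [29])
        assert res.per_event[0] == 6.0
        assert res.n_edge_clamped == 1

    def test_no_events_undefined(self):
        res = event_delay(np.zeros(50), np.zeros(50), [])
        assert np.isnan(res.mean)

    def test_average_event_delay_close_to_per_event_mean(self, coupled_series):
        series, truth = coupled_series
        ev = detect_events(series, "r0")
        tau = average_event_delay(series.column("r0"), series.column("r1"),
                                  ev.crossing_times)
        assert tau == pytest.approx(truth.lags[("r0", "r1")], abs=0.5)


class TestDelayMatrix:
    def test_pearson_matrix_exactly_antisymmetric(self, small_series):
        dm = delay_matrix(small_series, "pearson_lag", max_lag=8)
        np.testing.assert_array_equal(dm.values + dm.values.T,
                                      np.zeros_like(dm.values))

    def test_identical_columns_give_zero_lags(self, coupled_series):
        series, _ = coupled_series
        data = np.column_stack([series.data[:, 0]] * 2)
        s = RoiTimeSeries(data, tr=2.3, labels=("p", "q"), zscored=True)
        for method in ("pearson_lag", "event_lag"):
            dm = delay_matrix(s, method, max_lag=8)
            np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_event_matrix_recovers_coupling_and_stores_per_event(
            self, coupled_series):
        series, truth = coupled_series
        dm = delay_matrix(series, "event_lag", store_per_event=True)
        assert dm.values[0, 1] == pytest.approx(truth.lags[("r0", "r1")],
                                                abs=0.5)
        assert ("r0", "r2") in dm.per_event
        # independent pair's per-event lags scatter more than the coupled pair
        assert dm.per_event[("r0", "r2")].std() > \
            dm.per_event[("r0", "r1")].std()

    def test_lags_bounded_by_window(self, small_series):
        dm = delay_matrix(small_series, "event_lag")
        finite = dm.values[np.isfinite(dm.values)]
        assert np.all(np.abs(finite) <= 8)
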