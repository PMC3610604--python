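"""Stochastic bridge engine: stepping rules, protocols and sweeps."""

import numpy as np
import pytest

from antbridge.params import DEFAULT_PARAMS
from antbridge.simulator import (
    BridgeState,
    TrafficProtocol,
    mean_bridge_size_series,
    oscillation_sweep,
    poisson_sweep,
    replay_perturbation,
    simulate,
    square_wave_rate,
    step,
)


class TestStep:
    def test_zero_rate_empty_bridge_only_advances_clock(self):
        state = BridgeState(gap_length=15.0)
        tallies = step(state, 0.0, rng=np.random.default_rng(0))
        assert state.clock == 1.0
        assert not state.members
        assert tallies == {"joins": 0, "leaves": 0, "crossings": 0,
                           "bridge_size": 0}

    def test_certain_joining_absorbs_every_arrival(self):
        # alpha = 1 makes the join probability identically 1
        params = DEFAULT_PARAMS.replace(alpha=1.0, rho=1e9)
        state = BridgeState(gap_length=15.0)
        rng = np.random.default_rng(1)
        total_joins = 0
        for _ in range(50):
            tallies = step(state, 2.0, params, rng)
            assert tallies["crossings"] == 0
            total_joins += tallies["joins"]
        assert len(state.members) == total_joins > 0

    def test_arrival_counts_match_poisson_moments(self):
        state = BridgeState(gap_length=15.0)
        # joining disabled so arrivals == crossings
        params = DEFAULT_PARAMS.replace(alpha=0.0, beta=1e-9)
        rng = np.random.default_rng(2)
        n = 20000
        counts = [step(state, 2.0, params, rng)["crossings"] for _ in range(n)]
        se = np.sqrt(2.0 / n)
        assert np.mean(counts) == pytest.approx(2.0, abs=3 * se)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            step(BridgeState(gap_length=15.0), -1.0)


class TestSimulate:
    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_same_seed_reproduces_bitwise(self, engine):
        proto = TrafficProtocol(kind="constant", lam=1.5)
        a = simulate(proto, duration=150, seed=5, engine=engine)
        b = simulate(proto, duration=150, seed=5, engine=engine)
        assert np.array_equal(a.bridge_size, b.bridge_size)
        assert np.array_equal(a.crossings, b.crossings)

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_zero_traffic_never_builds_a_bridge(self, engine):
        res = simulate(TrafficProtocol(kind="constant", lam=0.0),
                       duration=200, seed=0, engine=engine)
        assert res.non_empty_ratio == 0.0
        assert res.bridge_size.max() == 0

    @pytest.mark.parametrize("engine,seed", [("numba", 3), ("numba", 4),
                                             ("python", 3), ("python", 4)])
    def test_conservation_joins_minus_leaves(self, engine, seed):
        res = simulate(TrafficProtocol(kind="constant", lam=2.0),
                       duration=300, seed=seed, engine=engine)
        sizes = np.concatenate([[0], res.bridge_size])
        assert np.array_equal(np.diff(sizes), res.joins - res.leaves)

    def test_engines_agree_statistically(self):
        # same rules, different random streams: mean occupancy must match
        reps = 60
        duration = 120
        numba_mean = mean_bridge_size_series(1.5, 15.0, duration,
                                             reps=reps, seed=0).mean()
        py = [simulate(TrafficProtocol(kind="constant", lam=1.5),
                       duration=duration, seed=1000 + r,
                       engine="python").bridge_size.mean()
              for r in range(reps)]
        se = np.std(py, ddof=1) / np.sqrt(reps)
        assert numba_mean == pytest.approx(np.mean(py), abs=4 * se + 0.05)

    def test_high_traffic_beats_low_traffic_occupancy(self):
        hi = np.mean([simulate(TrafficProtocol(kind="constant", lam=4.0),
                               duration=600, seed=s).non_empty_ratio
                      for s in range(20)])
        lo = np.mean([simulate(TrafficProtocol(kind="constant", lam=0.1),
                               duration=600, seed=s).non_empty_ratio
                      for s in range(20)])
        assert hi > lo + 0.5


class TestSquareWave:
    def test_zero_intensity_is_constant_flow(self):
        t = np.arange(40)
        assert np.allclose(square_wave_rate(t, 7, 0.0, 3.0), 3.0)

    def test_full_intensity_period_four_pattern(self):
        t = np.arange(8)
        rates = square_wave_rate(t, 4, 1.0, 3.0)
        assert np.array_equal(rates, [3, 3, 0, 0, 3, 3, 0, 0])

    def test_mean_over_even_period_is_half_depth(self):
        for period in (2, 4, 10, 20):
            t = np.arange(period)
            rates = square_wave_rate(t, period, 0.6, 3.0)
            assert np.mean(rates) == pytest.approx(3.0 * (1 - 0.6 / 2))

    def test_periodicity(self):
        t = np.arange(30, dtype=float)
        assert np.allclose(square_wave_rate(t, 6, 0.8),
                           square_wave_rate(t + 6, 6, 0.8))

    def test_intensity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            square_wave_rate(0.0, 4, 1.2)


class TestSweeps:
    def test_single_cell_sweep_reproduces_simulate(self):
        tab = poisson_sweep(lambdas=[1.2], reps=1, duration=300, seed=9)
        res = simulate(TrafficProtocol(kind="constant", lam=1.2),
                       duration=300, seed=9)
        assert tab["non_empty_ratio"].iloc[0] == pytest.approx(
            res.non_empty_ratio, abs=1e-12)

    def test_ratio_rises_from_low_to_moderate_traffic(self):
        tab = poisson_sweep(lambdas=[0.1, 0.5, 1.0, 1.5], reps=100,
                            duration=300, seed=2)
        r = tab["non_empty_ratio"].to_numpy()
        assert np.all(np.diff(r) > 0)
        assert r[-1] > r[0] + 0.5

    def test_oscillation_ratio_decreases_with_intensity(self):
        sw = oscillation_sweep(periods=[4, 10], intensities=[0.2, 0.6, 1.0],
                               reps=80, seed=3)
        for period in (4.0, 10.0):
            col = sw.table[sw.table.period == period].sort_values("intensity")
            r = col["non_empty_ratio"].to_numpy()
            assert r[0] > r[-1]
            assert np.all(np.diff(r) < 0.02)  # monotone up to replicate noise

    def test_oscillation_matrix_shape_and_argmax(self):
        sw = oscillation_sweep(periods=[2, 3, 8], intensities=[1.0],
                               reps=60, seed=4)
        assert sw.matrix.shape == (3, 1)
        assert sw.argmax_period[1.0] in (2.0, 3.0, 8.0)
        assert ((sw.table["non_empty_ratio"] >= 0)
                & (sw.table["non_empty_ratio"] <= 1)).all()

    def test_short_period_optimum_robust_to_gap_length(self):
        # the stability optimum stays in the short-period band whatever
        # the gap length (the bridge length only scales packing density)
        for gap in (5.0, 15.0, 30.0):
            sw = oscillation_sweep(periods=[1, 3, 5, 10, 16, 20],
                                   intensities=[1.0], reps=100,
                                   gap_length=gap, seed=6)
            assert sw.argmax_period[1.0] in (3.0, 5.0)


class TestReplay:
    def test_no_ants_no_traffic_stays_empty(self):
        sizes = replay_perturbation(np.zeros(50), initial_n=0, reps=3, seed=0)
        assert sizes.shape == (3, 50)
        assert not sizes.any()

    def test_stationary_under_constant_pre_sweep_traffic(self):
        # seeding at the stationary mean and replaying the same constant
        # traffic must not drift appreciably over a minute
        series = np.full(60, 2.0)
        sizes = replay_perturbation(series, initial_n=6, reps=300, seed=1)
        m = sizes.mean(axis=0)
        assert m[-10:].mean() == pytest.approx(m[:10].mean(), rel=0.2)

    def test_bridge_decays_with_decaying_traffic(self):
        t = np.arange(120)
        series = 2.0 * np.exp(-0.05 * t)
        sizes = replay_perturbation(series, initial_n=6, reps=200, seed=2)
        m = sizes.mean(axis=0)
        assert m[:10].mean() > 3 * m[-10:].mean()

    def test_negative_traffic_rejected(self):
        with pytest.raises(ValueError):
            replay_perturbation(np.array([1.0, -0.5]), initial_n=2)
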