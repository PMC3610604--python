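"""Behavioral rule functions and their fitting procedures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antbridge.model_core import (
    calibrate_share_params,
    expected_residence,
    fit_join_sigmoid,
    fit_residence_exponential,
    local_flow,
    p_join,
    p_leave,
    traffic_share,
)
from antbridge.params import BehaviorParams, DEFAULT_PARAMS


def _p_join_oracle(f, d, p=DEFAULT_PARAMS):
    # independent scalar evaluation of the join sigmoid
    return p.alpha + (1 - p.alpha) / (1 + math.exp(p.gamma * f + p.theta * d) / p.beta)


class TestJoinProbability:
    def test_heavy_traffic_floor_is_alpha(self):
        assert p_join(1e6, 0.0) == pytest.approx(0.02, abs=1e-12)
        assert p_join(10.0, 50.0) == pytest.approx(0.02, abs=1e-6)

    def test_empty_quiet_gap_approaches_one_for_large_beta(self):
        p = DEFAULT_PARAMS.replace(beta=1e9)
        assert p_join(0.0, 0.0, p) > 1 - 1e-6

    def test_matches_scalar_oracle(self):
        assert p_join(1.0, 0.5) == pytest.approx(_p_join_oracle(1.0, 0.5), rel=1e-12)

    @given(st.floats(0, 5), st.floats(0, 2))
    def test_bounded_between_alpha_and_one(self, f, d):
        p = p_join(f, d)
        assert DEFAULT_PARAMS.alpha <= p <= 1.0

    def test_monotone_decreasing_in_both_arguments(self):
        f = np.linspace(0, 4, 50)
        assert np.all(np.diff(p_join(f, 0.3)) < 0)
        d = np.linspace(0, 2, 50)
        assert np.all(np.diff(p_join(0.5, d)) < 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            p_join(-0.1, 0.0)
        with pytest.raises(ValueError):
            p_join(0.0, -0.1)


class TestResidenceAndLeaving:
    def test_residence_at_zero_flow_is_rho(self):
        assert expected_residence(0.0) == pytest.approx(1.959)

    def test_flow_increment_doubling_residence(self):
        # T(f + ln2/sigma) = 2 T(f) for every f
        df = math.log(2) / DEFAULT_PARAMS.sigma
        for f in [0.0, 0.4, 1.0]:
            assert expected_residence(f + df) == pytest.approx(
                2 * expected_residence(f), rel=1e-12)
        assert round(df, 2) == 0.25

    def test_sigma_zero_gives_constant_residence(self):
        p = DEFAULT_PARAMS.replace(sigma=0.0)
        flows = np.linspace(0, 3, 7)
        assert np.allclose(expected_residence(flows, p), p.rho)

    def test_leaving_is_reciprocal_residence(self):
        assert p_leave(0.0) == pytest.approx(1 / 1.959)
        assert p_leave(1.0) == pytest.approx(1 / (1.959 * math.e ** 2.789))

    def test_leaving_clamped_to_one_when_rho_below_one(self):
        p = DEFAULT_PARAMS.replace(rho=0.5)
        assert p_leave(0.0, p) == 1.0

    def test_residence_times_leave_probability_is_unity_where_unclamped(self):
        flows = np.linspace(0, 2, 21)
        prod = expected_residence(flows) * p_leave(flows)
        assert np.allclose(prod, 1.0)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            expected_residence(-1.0)
        with pytest.raises(ValueError):
            p_leave(-1.0)


class TestTrafficShare:
    def test_empty_bridge_gives_full_share(self):
        assert traffic_share(0.0) == 1.0

    def test_matches_scalar_oracle_at_density_two(self):
        expected = min(1.0, 3.0 * math.exp(-0.52 * 2.0 ** 2.0))
        assert traffic_share(2.0) == pytest.approx(expected, rel=1e-12)
        assert traffic_share(2.0) == pytest.approx(0.3748, abs=5e-4)

    def test_monotone_non_increasing_on_grid(self):
        d = np.linspace(0, 3, 100)
        s = traffic_share(d)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s > 0) & (s <= 1))

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            traffic_share(-0.5)


class TestLocalFlow:
    def test_zero_buffer_gives_zero(self):
        assert local_flow(0.5, [0, 0, 0, 0, 0]) == 0.0

    def test_full_share_recovers_buffer_mean(self):
        assert local_flow(0.0, [2, 2, 2, 2, 2]) == pytest.approx(2.0)

    def test_share_scales_buffer_mean(self):
        share = traffic_share(2.0)
        assert local_flow(2.0, [1, 2, 3, 4, 5]) == pytest.approx(share * 3.0)

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            local_flow(0.5, [])


@pytest.fixture(scope="module")
def bernoulli_events():
    # outcomes drawn straight from the sigmoid over a wide covariate grid
    rng = np.random.default_rng(42)
    n = 5000
    f = rng.uniform(0, 4, n)
    d = rng.uniform(0, 1.2, n)
    y = rng.random(n) < p_join(f, d)
    return pd.DataFrame({"traffic_at_arrival": f, "density_at_arrival": d,
                         "joined": y})


class TestJoinSigmoidFit:
    def test_recovers_generating_slopes(self, bernoulli_events):
        fit = fit_join_sigmoid(bernoulli_events, seed=0)
        assert fit.alpha == pytest.approx(DEFAULT_PARAMS.alpha, abs=0.02)
        assert fit.gamma == pytest.approx(DEFAULT_PARAMS.gamma, rel=0.20)
        assert fit.theta == pytest.approx(DEFAULT_PARAMS.theta, rel=0.20)

    def test_duplicated_events_give_identical_fit(self, bernoulli_events):
        fit1 = fit_join_sigmoid(bernoulli_events, seed=0)
        doubled = pd.concat([bernoulli_events, bernoulli_events],
                            ignore_index=True)
        fit2 = fit_join_sigmoid(doubled, seed=0)
        assert fit2.gamma == pytest.approx(fit1.gamma, rel=1e-4)
        assert fit2.theta == pytest.approx(fit1.theta, rel=1e-4)
        assert fit2.residual == pytest.approx(2 * fit1.residual, rel=1e-4)

    def test_constant_probability_limit_matches_empirical_rate(self):
        # joins independent of the covariates: the fitted curve must sit
        # at the empirical join rate on average
        rng = np.random.default_rng(7)
        n = 4000
        f = rng.uniform(0, 4, n)
        d = rng.uniform(0, 1, n)
        y = rng.random(n) < 0.1
        events = pd.DataFrame({"traffic_at_arrival": f,
                               "density_at_arrival": d, "joined": y})
        fit = fit_join_sigmoid(events, seed=1)
        params = BehaviorParams(alpha=fit.alpha, beta=fit.beta,
                                gamma=fit.gamma, theta=fit.theta)
        predicted = np.mean(p_join(f, d, params))
        assert predicted == pytest.approx(y.mean(), abs=0.03)

    def test_identical_outcomes_rejected(self):
        events = pd.DataFrame({"traffic_at_arrival": [1.0] * 60,
                               "density_at_arrival": np.linspace(0, 1, 60),
                               "joined": [True] * 60})
        with pytest.raises(ValueError, match="identifiable"):
            fit_join_sigmoid(events)


class TestResidenceFit:
    def test_noiseless_data_recovered_to_solver_tolerance(self):
        flows = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        times = 1.959 * np.exp(2.789 * flows)
        records = pd.DataFrame({"local_flow": flows, "residence_time": times})
        fit = fit_residence_exponential(records)
        assert fit.rho == pytest.approx(1.959, rel=1e-6)
        assert fit.sigma == pytest.approx(2.789, rel=1e-6)
        assert fit.residual < 1e-8

    def test_constant_times_give_zero_sigma(self):
        records = pd.DataFrame({"local_flow": np.linspace(0, 2, 30),
                                "residence_time": np.full(30, 5.0)})
        fit = fit_residence_exponential(records)
        assert fit.sigma == pytest.approx(0.0, abs=1e-6)
        assert fit.rho == pytest.approx(5.0, rel=1e-6)

    def test_constant_flow_rejected(self):
        records = pd.DataFrame({"local_flow": np.full(20, 0.7),
                                "residence_time": np.linspace(1, 10, 20)})
        with pytest.raises(ValueError, match="identifiable"):
            fit_residence_exponential(records)


class TestShareCalibration:
    def test_self_calibration_objective_not_worse_than_truth(self):
        from antbridge.simulator import mean_bridge_size_series
        target = mean_bridge_size_series(1.5, 15.0, 60, reps=100, seed=99)
        res = calibrate_share_params(
            target, lam=1.5, reps=50, seed=1,
            phi_grid=np.linspace(-1.5, 0.0, 4),
            psi_grid=np.linspace(1.0, 5.0, 4),
            omega_grid=np.linspace(1.0, 3.0, 3),
            refine=False,
        )
        # Monte-Carlo objective at the returned optimum must not exceed the
        # objective at the generating parameters by more than replicate noise
        truth = calibrate_share_params(
            target, lam=1.5, reps=50, seed=1,
            phi_grid=[DEFAULT_PARAMS.phi], psi_grid=[DEFAULT_PARAMS.psi],
            omega_grid=[DEFAULT_PARAMS.omega], refine=False,
        )
        assert res.mse <= truth.mse + 0.05
        assert res.rmse == pytest.approx(np.sqrt(res.mse))

    def test_zero_series_with_zero_traffic_is_degenerate(self):
        with pytest.warns(RuntimeWarning, match="flat"):
            res = calibrate_share_params(
                np.zeros(30), lam=0.0, reps=5, seed=0,
                phi_grid=[-1.0, -0.5], psi_grid=[1.0, 2.0],
                omega_grid=[1.0, 2.0], refine=False,
            )
        assert res.degenerate
        assert res.mse == 0.0
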