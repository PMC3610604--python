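"""Behavioral rule functions of the living-bridge model and their fitting.

Three rules drive the model.  A passing ant joins the bridge with
probability

    p_join(f, D) = alpha + (1 - alpha) / (1 + (1/beta) * exp(gamma*f + theta*D))

a bivariate logistic, decreasing both in the trail traffic ``f`` (ants/s)
and in the bridge packing density ``D`` (ants/mm), with lower asymptote
``alpha``.  A member's expected residence time grows exponentially with
the local traffic over its body,

    T(f_local) = rho * exp(sigma * f_local)

so its per-second leaving probability is the clamped reciprocal
``min(1, 1/T)``.  The local traffic is the member's traffic share —
a decreasing function ``min(1, psi*exp(phi*D_join^omega))`` of the packing
density at the moment it joined — times the mean per-second crossing count
over the last ``m`` seconds.

The fitting procedures mirror how the parameters were estimated from
removal-experiment event records: least squares of 0/1 join outcomes on
the sigmoid, nonlinear least squares of residence times on the
exponential, and a simulation-based calibration of the share parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import BehaviorParams, DEFAULT_PARAMS

__all__ = [
    "p_join",
    "expected_residence",
    "p_leave",
    "traffic_share",
    "local_flow",
    "fit_join_sigmoid",
    "fit_residence_exponential",
    "calibrate_share_params",
    "JoinFitResult",
    "ResidenceFitResult",
    "ShareCalibrationResult",
]

_EXP_MAX = 700.0  # exp overflow guard; beyond this the sigmoid is saturated anyway


def _check_nonneg(name: str, x: np.ndarray | float) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def p_join(
    traffic: np.ndarray | float,
    density: np.ndarray | float,
    params: BehaviorParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """Probability that a passing ant stops to join the bridge.

    Parameters
    ----------
    traffic : array_like
        Instantaneous traffic intensity on the trail (ants/s, >= 0).
    density : array_like
        Current packing density of the bridge (ants/mm, >= 0).

    Returns
    -------
    Probability in ``[alpha, 1]``, strictly decreasing in both arguments.
    """
    f = _check_nonneg("traffic", traffic)
    d = _check_nonneg("density", density)
    z = np.clip(params.gamma * f + params.theta * d, -_EXP_MAX, _EXP_MAX)
    p = params.alpha + (1.0 - params.alpha) / (1.0 + np.exp(z) / params.beta)
    return p if p.ndim else float(p)


def expected_residence(
    local_flow: np.ndarray | float,
    params: BehaviorParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """Expected time (s) an ant stays in the bridge at a given local flow.

    ``rho * exp(sigma * local_flow)``, strictly increasing in the flow
    (for ``sigma > 0``).  At zero flow this is ``rho`` seconds.
    """
    f = _check_nonneg("local_flow", local_flow)
    t = params.rho * np.exp(np.clip(params.sigma * f, None, _EXP_MAX))
    return t if t.ndim else float(t)


def p_leave(
    mean_local_flow: np.ndarray | float,
    params: BehaviorParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """Per-second probability that a bridge member leaves.

    The clamped reciprocal of the expected residence time:
    ``min(1, 1 / (rho * exp(sigma * f)))``, non-increasing in the flow.
    """
    t = expected_residence(mean_local_flow, params)
    p = np.minimum(1.0, 1.0 / np.asarray(t, dtype=float))
    return p if p.ndim else float(p)


def traffic_share(
    density_at_join: np.ndarray | float,
    params: BehaviorParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """Fraction of bridge traffic passing over one member's body.

    ``min(1, psi * exp(phi * D^omega))`` of the packing density at the
    moment the ant joined; ants joining an emptier bridge intercept a
    larger share.  Monotone non-increasing for ``phi < 0``.
    """
    d = _check_nonneg("density_at_join", density_at_join)
    z = np.clip(params.phi * np.power(d, params.omega), -_EXP_MAX, _EXP_MAX)
    s = np.minimum(1.0, params.psi * np.exp(z))
    return s if s.ndim else float(s)


def local_flow(
    density_at_join: float,
    recent_crossings: Sequence[float] | np.ndarray,
    params: BehaviorParams = DEFAULT_PARAMS,
) -> float:
    """Local traffic over one member: share x mean recent crossing count.

    ``recent_crossings`` is the buffer of per-second gap-crossing counts
    over the last ``m`` seconds (padded to length ``m`` upstream).
    """
    buf = np.asarray(recent_crossings, dtype=float)
    if buf.size == 0:
        raise ValueError("recent_crossings buffer is empty")
    share = traffic_share(density_at_join, params)
    return float(share * buf.mean())


# ---------------------------------------------------------------------------
# Fitting procedures
# ---------------------------------------------------------------------------

@dataclass
class JoinFitResult:
    alpha: float
    beta: float
    gamma: float
    theta: float
    residual: float  # sum of squared residuals of 0/1 outcomes
    n_events: int
    seed: int

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.theta)


@dataclass
class ResidenceFitResult:
    rho: float
    sigma: float
    residual: float
    n_records: int


@dataclass
class ShareCalibrationResult:
    phi: float
    psi: float
    omega: float
    mse: float          # mean squared difference, ants^2
    rmse: float         # its square root, ants
    degenerate: bool    # True when the objective is flat (e.g. all-zero target)
    seed: int


def _join_design(events: pd.DataFrame | Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(events, pd.DataFrame):
        f = events["traffic_at_arrival"].to_numpy(dtype=float)
        d = events["density_at_arrival"].to_numpy(dtype=float)
        y = events["joined"].to_numpy(dtype=float)
    else:
        f = np.asarray([e.traffic_at_arrival for e in events], dtype=float)
        d = np.asarray([e.density_at_arrival for e in events], dtype=float)
        y = np.asarray([float(e.joined) for e in events], dtype=float)
    return f, d, y


def fit_join_sigmoid(
    events: pd.DataFrame | Sequence,
    seed: int = 0,
    n_starts: int = 8,
) -> JoinFitResult:
    """Fit the join sigmoid to success/failure records by least squares.

    Minimizes ``sum((joined_i - p_join(f_i, D_i))^2)`` over
    ``(alpha, beta, gamma, theta)`` with multi-start local optimization
    (deterministic for a fixed ``seed``).  ``beta`` is optimized on a log
    scale.  Raises if the outcomes are all identical (the curve's shape is
    then unidentifiable).
    """
    f, d, y = _join_design(events)
    if len(y) < 2:
        raise ValueError("need at least two events")
    if np.all(y == y[0]):
        raise ValueError("all outcomes identical: join sigmoid is not identifiable")

    def resid(x: np.ndarray) -> np.ndarray:
        alpha, logbeta, gamma, theta = x
        z = np.clip(gamma * f + theta * d - logbeta, -_EXP_MAX, _EXP_MAX)
        p = alpha + (1.0 - alpha) / (1.0 + np.exp(z))
        return p - y

    rng = np.random.default_rng(seed)
    x0_base = np.array([0.05, np.log(100.0), 1.0, 5.0])
    lb = np.array([0.0, -10.0, 0.0, 0.0])
    ub = np.array([1.0, 20.0, 50.0, 200.0])
    best = None
    for k in range(n_starts):
        if k == 0:
            x0 = x0_base
        else:
            x0 = np.array([
                rng.uniform(0.0, 0.2),
                rng.uniform(0.0, 8.0),
                rng.uniform(0.1, 10.0),
                rng.uniform(0.1, 40.0),
            ])
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lb, ub), ftol=1e-8, xtol=1e-10, gtol=1e-10
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("join sigmoid fit failed from every start")
    alpha, logbeta, gamma, theta = best.x
    rss = float(2.0 * best.cost)
    return JoinFitResult(float(alpha), float(np.exp(logbeta)), float(gamma),
                         float(theta), rss, len(y), seed)


def fit_residence_exponential(
    records: pd.DataFrame | Sequence,
) -> ResidenceFitResult:
    """Fit ``residence_time ~ rho * exp(sigma * local_flow)`` by NLS.

    Raises when all flow values coincide (``sigma`` unidentifiable).
    """
    if isinstance(records, pd.DataFrame):
        flow = records["local_flow"].to_numpy(dtype=float)
        t = records["residence_time"].to_numpy(dtype=float)
    else:
        flow = np.asarray([r.local_flow for r in records], dtype=float)
        t = np.asarray([r.residence_time for r in records], dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two records")
    if np.ptp(flow) == 0:
        raise ValueError("all local_flow values identical: sigma is not identifiable")
    if np.any(t <= 0):
        raise ValueError("residence times must be positive")

    # log-linear start, then NLS on the original scale
    b, a = np.polyfit(flow, np.log(t), 1)
    p0 = [float(np.exp(a)), max(float(b), 0.0)]

    def model(x, rho, sigma):
        return rho * np.exp(np.clip(sigma * x, None, _EXP_MAX))

    popt, _ = optimize.curve_fit(
        model, flow, t, p0=p0, bounds=([1e-12, 0.0], [np.inf, 50.0]),
        maxfev=20000,
    )
    rss = float(np.sum((model(flow, *popt) - t) ** 2))
    return ResidenceFitResult(float(popt[0]), float(popt[1]), rss, len(t))


def calibrate_share_params(
    observed_mean_bridge_size: np.ndarray | Sequence[float],
    gap_length: float = 15.0,
    lam: float = 1.5,
    params: BehaviorParams = DEFAULT_PARAMS,
    reps: int = 200,
    seed: int = 0,
    phi_grid: np.ndarray | None = None,
    psi_grid: np.ndarray | None = None,
    omega_grid: np.ndarray | None = None,
    refine: bool = True,
) -> ShareCalibrationResult:
    """Calibrate the share parameters against a mean bridge-size series.

    Grid search over ``(phi, psi, omega)`` followed by local (Nelder-Mead)
    refinement, minimizing the mean squared difference (ants^2) between the
    observed per-second mean bridge size and the mean over ``reps`` seeded
    simulations under constant traffic ``lam`` on a gap of ``gap_length``
    mm.  Common random numbers (a fixed replicate seed set) keep the
    objective deterministic.  Both the mean squared difference and its
    square root are reported.
    """
    from .simulator import mean_bridge_size_series  # local import: avoid cycle

    target = np.asarray(observed_mean_bridge_size, dtype=float)
    if target.size < 2:
        raise ValueError("observed series too short")
    duration = int(target.size)

    if phi_grid is None:
        phi_grid = np.linspace(-2.0, 0.0, 11)
    if psi_grid is None:
        psi_grid = np.linspace(0.5, 5.0, 11)
    if omega_grid is None:
        omega_grid = np.linspace(0.5, 4.0, 11)

    def objective(x: np.ndarray) -> float:
        phi, psi, omega = x
        if psi <= 0 or omega <= 0:
            return np.inf
        p = params.replace(phi=float(phi), psi=float(psi), omega=float(omega))
        mean_series = mean_bridge_size_series(
            lam=lam, gap_length=gap_length, duration=duration,
            params=p, reps=reps, seed=seed,
        )
        return float(np.mean((mean_series - target) ** 2))

    best_x, best_val = None, np.inf
    values = []
    for phi in phi_grid:
        for psi in psi_grid:
            for omega in omega_grid:
                v = objective(np.array([phi, psi, omega]))
                values.append(v)
                if v < best_val:
                    best_val, best_x = v, np.array([phi, psi, omega])

    degenerate = bool(np.ptp(values) < 1e-12)
    if degenerate:
        warnings.warn("calibration objective is flat across the grid; "
                      "returning the grid minimum", RuntimeWarning)
    elif refine:
        sol = optimize.minimize(
            objective, best_x, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 200},
        )
        if sol.fun <= best_val:
            best_x, best_val = sol.x, float(sol.fun)

    phi, psi, omega = (float(v) for v in best_x)
    return ShareCalibrationResult(phi, psi, omega, float(best_val),
                                  float(np.sqrt(best_val)), degenerate, seed)
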