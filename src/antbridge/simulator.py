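"""Time-stepped stochastic engine for living-bridge self-assembly.

Each one-second step, a Poisson number of ants reaches the gap.  Every
arrival either stops to join the bridge (with the join sigmoid evaluated
at the instantaneous trail rate and the current packing density, updated
after each join) or crosses.  All members then decide simultaneously
whether to leave, each from the mean per-second crossing count over the
last ``m`` seconds scaled by its individual traffic share.  Crossing
counts exclude joiners.

Two engines implement identical rules: a readable Python engine (this
module; supports per-event logging for the synthetic-data generator) and
a numba kernel (:mod:`antbridge._engine`) used by the sweeps.  Each is
bit-reproducible under a fixed seed; their random streams differ, so
results agree statistically rather than bitwise across engines.

The three protocols mirror the study design: constant Poisson traffic
(stability vs. traffic intensity), a square-wave oscillation of given
period and intensity run for 100 oscillation periods (stability vs.
naturalistic traffic fluctuations), and replay of a recorded per-second
traffic series into a pre-seeded bridge (responsiveness to sudden traffic
interruption).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .model_core import p_join, p_leave, traffic_share
from .params import BehaviorParams, DEFAULT_PARAMS

__all__ = [
    "AntState",
    "BridgeState",
    "TrafficProtocol",
    "SimulationResult",
    "EventLog",
    "step",
    "simulate",
    "square_wave_rate",
    "poisson_sweep",
    "oscillation_sweep",
    "OscillationSweepResult",
    "replay_perturbation",
    "mean_bridge_size_series",
]


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class AntState:
    """One bridge member: its join context and traffic-flow memory."""
    id: int
    join_time: float
    density_at_join: float
    share: float
    flow_memory: deque  # last m per-second crossing counts (global counts)
    flow_sum: float = 0.0    # accumulated local flow over the stay
    flow_steps: int = 0

    def local_flow(self) -> float:
        if not self.flow_memory:
            return 0.0
        return self.share * float(np.mean(self.flow_memory))


@dataclass
class BridgeState:
    gap_length: float
    members: list[AntState] = field(default_factory=list)
    clock: float = 0.0
    crossing_history: list[int] = field(default_factory=list)
    next_id: int = 0

    def __post_init__(self) -> None:
        if self.gap_length <= 0:
            raise ValueError("gap_length must be positive")

    @property
    def density(self) -> float:
        return len(self.members) / self.gap_length

    def padded_memory(self, m: int) -> deque:
        """Last ``m`` crossing counts, padded with the first observed value."""
        hist = self.crossing_history
        if not hist:
            return deque([0.0] * m, maxlen=m)
        tail = hist[-m:]
        pad = [float(hist[0])] * (m - len(tail))
        return deque(pad + [float(v) for v in tail], maxlen=m)


@dataclass
class TrafficProtocol:
    """Per-second arrival-rate generator.

    kind='constant' uses ``lam``; kind='square_wave' oscillates between
    ``max_rate`` and ``max_rate*(1-intensity)`` with the given period;
    kind='replay' replays an explicit per-second ``series``.
    """
    kind: str = "constant"
    lam: float = 1.5
    period: float = 3.0
    intensity: float = 1.0
    max_rate: float = 3.0
    series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "square_wave", "replay"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "constant" and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.kind == "square_wave":
            if not 0.0 <= self.intensity <= 1.0:
                raise ValueError("intensity must be in [0, 1]")
            if self.period < 1:
                raise ValueError("period must be >= 1 s")
            if self.max_rate < 0:
                raise ValueError("max_rate must be >= 0")
        if self.kind == "replay":
            if self.series is None or len(self.series) == 0:
                raise ValueError("replay protocol needs a non-empty series")
            s = np.asarray(self.series, dtype=float)
            if np.any(s < 0) or np.any(~np.isfinite(s)):
                raise ValueError("replay series must be finite and >= 0")
            self.series = s

    def default_duration(self) -> int:
        if self.kind == "replay":
            return len(self.series)
        if self.kind == "square_wave":
            return int(round(100 * self.period))  # 100 oscillation periods
        return 600

    def rates(self, duration: int) -> np.ndarray:
        t = np.arange(duration, dtype=float)
        if self.kind == "constant":
            return np.full(duration, float(self.lam))
        if self.kind == "square_wave":
            return square_wave_rate(t, self.period, self.intensity, self.max_rate)
        out = np.zeros(duration)
        k = min(duration, len(self.series))
        out[:k] = self.series[:k]
        return out


@dataclass
class SimulationResult:
    """Per-second trajectories of one simulated bridge."""
    bridge_size: np.ndarray
    crossings: np.ndarray
    joins: np.ndarray
    leaves: np.ndarray
    gap_length: float
    seed: int

    @property
    def non_empty_ratio(self) -> float:
        """Fraction of seconds with at least one ant stopped in the gap."""
        return float(np.mean(self.bridge_size > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": np.arange(len(self.bridge_size)),
            "bridge_size": self.bridge_size,
            "crossings": self.crossings,
            "joins": self.joins,
            "leaves": self.leaves,
        })


@dataclass
class EventLog:
    """Per-event records collected by the Python engine."""
    arrivals: list = field(default_factory=list)   # dicts: time, traffic, density, joined
    departures: list = field(default_factory=list)  # dicts: ant_id, join_time, residence, mean local flow


# ---------------------------------------------------------------------------
# Python reference engine
# ---------------------------------------------------------------------------

def step(
    state: BridgeState,
    rate: float,
    params: BehaviorParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
    log: EventLog | None = None,
) -> dict:
    """Advance the bridge by one second under arrival rate ``rate``.

    Returns the per-step tallies ``{"joins", "leaves", "crossings",
    "bridge_size"}``; mutates ``state`` in place.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng()

    m = params.m
    n_arrivals = int(rng.poisson(rate)) if rate > 0 else 0

    joins = 0
    crossings = 0
    for _ in range(n_arrivals):
        d = state.density
        p = p_join(rate, d, params)
        joined = bool(rng.random() < p)
        if log is not None:
            log.arrivals.append({
                "time": state.clock, "traffic_at_arrival": rate,
                "density_at_arrival": d, "joined": joined,
            })
        if joined:
            ant = AntState(
                id=state.next_id, join_time=state.clock, density_at_join=d,
                share=float(traffic_share(d, params)),
                flow_memory=state.padded_memory(m),
            )
            state.next_id += 1
            state.members.append(ant)
            joins += 1
        else:
            crossings += 1

    # simultaneous leaving decisions from the pre-step memory
    stay: list[AntState] = []
    leaves = 0
    for ant in state.members:
        f = ant.local_flow()
        ant.flow_sum += f
        ant.flow_steps += 1
        if rng.random() < p_leave(f, params):
            leaves += 1
            if log is not None:
                log.departures.append({
                    "ant_id": ant.id,
                    "join_time": ant.join_time,
                    "residence_time": state.clock + 1.0 - ant.join_time,
                    "local_flow": ant.flow_sum / ant.flow_steps,
                    "density_at_join": ant.density_at_join,
                })
        else:
            stay.append(ant)
    state.members = stay

    state.crossing_history.append(crossings)
    for ant in state.members:
        ant.flow_memory.append(float(crossings))
    state.clock += 1.0

    return {
        "joins": joins, "leaves": leaves, "crossings": crossings,
        "bridge_size": len(state.members),
    }


def _init_state(gap_length: float, initial_n: int, initial_traffic: float,
                params: BehaviorParams) -> BridgeState:
    state = BridgeState(gap_length=gap_length)
    if initial_n > 0:
        # initial members joined sequentially onto an empty gap, under
        # traffic constant at initial_traffic for the preceding m seconds
        for i in range(initial_n):
            d = i / gap_length
            ant = AntState(
                id=state.next_id, join_time=0.0, density_at_join=d,
                share=float(traffic_share(d, params)),
                flow_memory=deque([float(initial_traffic)] * params.m,
                                  maxlen=params.m),
            )
            state.next_id += 1
            state.members.append(ant)
        state.crossing_history = [int(round(initial_traffic))] * params.m
    return state


def _kernel_seeds(seed: int, start: int, n: int) -> np.ndarray:
    """Derive ``n`` 31-bit kernel seeds from (master seed, replicate index).

    Replicate ``i`` of any run always maps to ``SeedSequence([seed, i])``,
    so a one-replicate sweep cell reproduces :func:`simulate` exactly with
    the same master seed.
    """
    return np.array(
        [np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31
         for i in range(start, start + n)],
        dtype=np.int64,
    )


def simulate(
    protocol: TrafficProtocol,
    gap_length: float = 15.0,
    duration: int | None = None,
    params: BehaviorParams = DEFAULT_PARAMS,
    seed: int = 0,
    initial_n: int = 0,
    initial_traffic: float = 0.0,
    engine: str = "numba",
    log: EventLog | None = None,
) -> SimulationResult:
    """Run one bridge simulation from an empty (or pre-seeded) gap.

    Fully reproducible for a fixed ``seed`` and engine.  ``engine='python'``
    uses the reference engine and supports event logging.
    """
    if duration is None:
        duration = protocol.default_duration()
    if duration < 1:
        raise ValueError("duration must be >= 1 s")
    rates = protocol.rates(duration)

    if engine == "numba":
        if log is not None:
            raise ValueError("event logging requires engine='python'")
        p = params
        size = np.empty(duration, np.int64)
        cross = np.empty(duration, np.int64)
        joins = np.empty(duration, np.int64)
        leaves = np.empty(duration, np.int64)
        _engine.run_kernel(
            rates, gap_length, p.alpha, p.beta, p.gamma, p.theta,
            p.rho, p.sigma, p.phi, p.psi, p.omega, p.m,
            int(_kernel_seeds(seed, 0, 1)[0]), initial_n, float(initial_traffic),
            size, cross, joins, leaves,
        )
        return SimulationResult(size, cross, joins, leaves, gap_length, seed)

    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")
    rng = np.random.default_rng(seed)
    state = _init_state(gap_length, initial_n, initial_traffic, params)
    size = np.empty(duration, np.int64)
    cross = np.empty(duration, np.int64)
    joins = np.empty(duration, np.int64)
    leaves = np.empty(duration, np.int64)
    for t in range(duration):
        tallies = step(state, float(rates[t]), params, rng, log)
        size[t] = tallies["bridge_size"]
        cross[t] = tallies["crossings"]
        joins[t] = tallies["joins"]
        leaves[t] = tallies["leaves"]
    return SimulationResult(size, cross, joins, leaves, gap_length, seed)


# ---------------------------------------------------------------------------
# Protocols and sweeps
# ---------------------------------------------------------------------------

def square_wave_rate(
    t: np.ndarray | float,
    period: float,
    intensity: float,
    max_rate: float = 3.0,
) -> np.ndarray | float:
    """Square-wave traffic rate at time ``t`` (s).

    The first half-period runs at ``max_rate``, the second at
    ``max_rate * (1 - intensity)``; intensity 0 is constant flow and 1 is
    full on/off.  Periodic in ``t`` with the given period.
    """
    if period < 1:
        raise ValueError("period must be >= 1 s")
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    tt = np.asarray(t, dtype=float)
    high = np.mod(tt, period) < period / 2.0
    out = np.where(high, max_rate, max_rate * (1.0 - intensity))
    return out if out.ndim else float(out)


def _kernel_args(params: BehaviorParams) -> tuple:
    p = params
    return (p.alpha, p.beta, p.gamma, p.theta, p.rho, p.sigma,
            p.phi, p.psi, p.omega, p.m)


def poisson_sweep(
    lambdas: Sequence[float] | np.ndarray | None = None,
    reps: int = 1000,
    duration: int = 600,
    gap_length: float = 15.0,
    params: BehaviorParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean non-empty bridge time ratio across a grid of Poisson rates.

    Defaults follow the stability analysis: rates 0.1 to 4 ants/s in
    0.05 steps, 1000 replicates of 600 s each on a 15 mm gap.
    """
    if lambdas is None:
        lambdas = np.round(np.arange(0.1, 4.0 + 1e-9, 0.05), 3)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid is empty")
    rows = []
    for i, lam in enumerate(lambdas):
        rates = np.full(duration, lam)
        seeds = _kernel_seeds(seed, i * reps, reps)
        ratios = _engine.ratios_over_reps(rates, gap_length,
                                          *_kernel_args(params), seeds)
        rows.append({
            "lam": float(lam),
            "non_empty_ratio": float(np.mean(ratios)),
            "sd": float(np.std(ratios)),
            "reps": reps,
        })
    return pd.DataFrame(rows)


@dataclass
class OscillationSweepResult:
    """Heatmap of bridge stability under square-wave traffic."""
    table: pd.DataFrame          # long format: period, intensity, non_empty_ratio
    matrix: pd.DataFrame         # periods x intensities
    argmax_period: dict          # intensity -> period with highest mean ratio

    def to_long(self) -> pd.DataFrame:
        return self.table


def oscillation_sweep(
    periods: Sequence[float] | None = None,
    intensities: Sequence[float] | None = None,
    reps: int = 1000,
    n_periods: int = 100,
    gap_length: float = 15.0,
    max_rate: float = 3.0,
    params: BehaviorParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> OscillationSweepResult:
    """Sweep square-wave period x intensity; each run lasts 100 periods.

    Returns the stability heatmap (mean non-empty bridge time ratio) and
    the period maximizing it within each intensity column.
    """
    if periods is None:
        periods = np.arange(1, 21)
    if intensities is None:
        intensities = np.linspace(0.0, 1.0, 11)
    periods = np.asarray(periods, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if periods.size == 0 or intensities.size == 0:
        raise ValueError("period/intensity grids must be non-empty")

    rows = []
    idx = 0
    for period in periods:
        duration = int(round(n_periods * period))
        t = np.arange(duration, dtype=float)
        for intensity in intensities:
            rates = np.asarray(square_wave_rate(t, period, intensity, max_rate))
            seeds = _kernel_seeds(seed, idx * reps, reps)
            idx += 1
            ratios = _engine.ratios_over_reps(rates, gap_length,
                                              *_kernel_args(params), seeds)
            rows.append({
                "period": float(period),
                "intensity": float(intensity),
                "non_empty_ratio": float(np.mean(ratios)),
                "sd": float(np.std(ratios)),
                "reps": reps,
            })
    table = pd.DataFrame(rows)
    matrix = table.pivot(index="period", columns="intensity",
                         values="non_empty_ratio")
    argmax = {
        float(col): float(matrix[col].idxmax()) for col in matrix.columns
    }
    return OscillationSweepResult(table, matrix, argmax)


def replay_perturbation(
    observed_traffic: Sequence[float] | np.ndarray,
    initial_n: int,
    gap_length: float = 15.0,
    params: BehaviorParams = DEFAULT_PARAMS,
    reps: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Replay a recorded traffic series into a pre-seeded bridge.

    The bridge starts with ``initial_n`` members assumed to have joined
    sequentially onto an empty gap, each with its flow memory filled with
    the traffic level at the start of the series.  Returns the per-second
    bridge-size series of every replicate, shape ``(reps, T)``.
    """
    series = np.asarray(observed_traffic, dtype=float)
    if series.size == 0:
        raise ValueError("observed traffic series is empty")
    if np.any(series < 0) or np.any(~np.isfinite(series)):
        raise ValueError("traffic values must be finite and >= 0")
    if initial_n < 0:
        raise ValueError("initial_n must be >= 0")
    seeds = _kernel_seeds(seed, 0, reps)
    return np.asarray(_engine.replay_over_reps(
        series, gap_length, *_kernel_args(params),
        seeds, int(initial_n), float(series[0]),
    ))


def mean_bridge_size_series(
    lam: float,
    gap_length: float,
    duration: int,
    params: BehaviorParams = DEFAULT_PARAMS,
    reps: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per-second mean bridge size under constant traffic, over replicates.

    This is the summary the share-parameter calibration matches against
    the observed reconstruction dynamics.
    """
    rates = np.full(int(duration), float(lam))
    seeds = _kernel_seeds(seed, 0, reps)
    return np.asarray(_engine.mean_size_over_reps(
        rates, gap_length, *_kernel_args(params), seeds,
    ))
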