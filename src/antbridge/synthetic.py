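"""Synthetic inputs with the statistical structure the analyses assume.

Every stage of the pipeline can be exercised without field recordings:
removal-experiment event tables come from the simulator itself run with
known ground-truth parameters (so recovery tests are self-describing),
trail-traffic traces carry an injected oscillation of known period,
perturbation series decay exponentially the way swept trails do, caste
tables reproduce the printed field counts or draw from a multinomial, and
translating-texture frame stacks provide a ground-truth optical-flow
fixture.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import expected_residence
from .params import BehaviorParams, DEFAULT_PARAMS
from .signal_analysis import CasteCounts, TrafficTrace
from .simulator import EventLog, TrafficProtocol, simulate
from .optical_flow import FrameWindow

__all__ = [
    "generate_removal_experiment",
    "generate_residence_table",
    "generate_trail_trace",
    "generate_perturbation_trace",
    "generate_caste_table",
    "generate_translating_frames",
    "PRINTED_CASTE_COUNTS",
]

# caste counts of the three structure contexts as printed in the field study
PRINTED_CASTE_COUNTS: dict[str, dict[str, int]] = {
    "bridge": {"minor": 293, "media": 582, "other": 45},     # n = 920
    "bivouac": {"minor": 193, "media": 356, "other": 24},    # n = 573
    "raid": {"minor": 729, "media": 2471, "other": 114},     # n = 3314
}

_CASTES = ("minor", "media", "submajor", "major")


def generate_removal_experiment(
    params: BehaviorParams = DEFAULT_PARAMS,
    gap_length: float = 15.0,
    duration: int = 120,
    lam: float = 1.5,
    lambda_range: tuple[float, float] | None = None,
    n_events: int | None = None,
    max_episodes: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulated removal-experiment records with known ground truth.

    Runs the model from an empty gap for ``duration``-second episodes,
    logging every arrival's covariates and join outcome and every
    leaver's residence time with its realized mean local flow.  With
    ``lambda_range`` set, each episode draws its own constant traffic
    intensity uniformly from the range (traffic variation across episodes
    is what identifies the traffic slope of the join sigmoid); episodes
    accumulate until ``n_events`` arrivals are logged.  Ground-truth
    parameters travel in each table's ``attrs``.

    Returns ``(join_events, residence_records, bridge_size_series)``.
    """
    rng = np.random.default_rng(seed)
    arrivals: list[dict] = []
    departures: list[dict] = []
    sizes: list[pd.DataFrame] = []

    episode = 0
    while True:
        if lambda_range is not None:
            lam_ep = float(rng.uniform(*lambda_range))
        else:
            lam_ep = float(lam)
        log = EventLog()
        res = simulate(
            TrafficProtocol(kind="constant", lam=lam_ep),
            gap_length=gap_length, duration=duration, params=params,
            seed=int(rng.integers(2**31)), engine="python", log=log,
        )
        for a in log.arrivals:
            a["episode"] = episode
        for d in log.departures:
            d["episode"] = episode
        arrivals.extend(log.arrivals)
        departures.extend(log.departures)
        df = res.to_frame()
        df["episode"] = episode
        sizes.append(df)
        episode += 1
        if n_events is None or len(arrivals) >= n_events or episode >= max_episodes:
            break

    join_events = pd.DataFrame(
        arrivals, columns=["episode", "time", "traffic_at_arrival",
                           "density_at_arrival", "joined"])
    join_events.insert(0, "ant_id", np.arange(len(join_events)))
    if n_events is not None:
        join_events = join_events.iloc[:n_events].copy()

    residence = pd.DataFrame(
        departures, columns=["episode", "ant_id", "join_time",
                             "residence_time", "local_flow", "density_at_join"])
    if len(residence):
        # plumbing covariates of the field protocol not used by the model
        nb = rng.poisson(2.0 + 3.0 * residence["density_at_join"].to_numpy())
        residence["n_neighbours"] = nb
        residence["position_class"] = np.where(nb >= 2, "centre", "edge")
        props = np.array([293, 582, 30, 15], dtype=float)
        residence["caste"] = rng.choice(_CASTES, size=len(residence),
                                        p=props / props.sum())
    else:
        residence["n_neighbours"] = pd.Series(dtype=int)
        residence["position_class"] = pd.Series(dtype=str)
        residence["caste"] = pd.Series(dtype=str)

    size_series = pd.concat(sizes, ignore_index=True) if sizes else pd.DataFrame()

    truth = params.to_dict()
    for df in (join_events, residence, size_series):
        df.attrs["true_params"] = truth
        df.attrs["gap_length"] = gap_length
        df.attrs["seed"] = seed
    return join_events, residence, size_series


def generate_residence_table(
    n: int = 1000,
    rho: float = DEFAULT_PARAMS.rho,
    sigma: float = DEFAULT_PARAMS.sigma,
    flow_range: tuple[float, float] = (0.0, 1.0),
    noise: str = "exponential",
    seed: int = 0,
) -> pd.DataFrame:
    """Residence records drawn directly around the exponential curve.

    Local flows are uniform on ``flow_range``; residence times are
    exponential (or deterministic, ``noise='none'``) with mean
    ``rho * exp(sigma * flow)``.  Used for residence-fit recovery checks.
    """
    rng = np.random.default_rng(seed)
    flow = rng.uniform(*flow_range, size=n)
    mean = rho * np.exp(sigma * flow)
    if noise == "exponential":
        t = rng.exponential(mean)
    elif noise == "none":
        t = mean
    else:
        raise ValueError(f"unknown noise kind {noise!r}")
    t = np.maximum(t, 1e-9)
    df = pd.DataFrame({
        "ant_id": np.arange(n),
        "residence_time": t,
        "local_flow": flow,
    })
    df.attrs["true_params"] = {"rho": rho, "sigma": sigma}
    df.attrs["seed"] = seed
    return df


def generate_trail_trace(
    period: float = 3.4,
    depth: float = 0.5,
    mean_level: float = 1.0,
    rate_hz: float = 25.0,
    duration: float = 120.0,
    waveform: str = "sine",
    noise: str = "gaussian",
    noise_level: float = 0.1,
    seed: int = 0,
) -> TrafficTrace:
    """Oscillating traffic trace emulating a foraging-trail recording.

    A sine or square oscillation of the given ``period`` (s) and relative
    ``depth`` around ``mean_level``, sampled at ``rate_hz``, with Gaussian
    or Poisson (shot) noise.  Sampling below twice the oscillation
    frequency raises (aliasing).
    """
    if period <= 0 or rate_hz <= 0 or duration <= 0:
        raise ValueError("period, rate_hz and duration must be positive")
    if rate_hz < 2.0 / period:
        raise ValueError("sampling rate below 2/period would alias the oscillation")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / rate_hz)
    phase = 2.0 * np.pi * t / period
    if waveform == "sine":
        osc = np.sin(phase)
    elif waveform == "square":
        osc = np.sign(np.sin(phase))
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    v = mean_level * (1.0 + depth * osc)
    if noise == "gaussian":
        v = v + noise_level * mean_level * rng.standard_normal(len(t))
    elif noise == "poisson":
        v = rng.poisson(np.maximum(v, 0.0)).astype(float)
    elif noise != "none":
        raise ValueError(f"unknown noise kind {noise!r}")
    return TrafficTrace(t, v)


def generate_perturbation_trace(
    lam0: float = 2.0,
    decay: float = 0.05,
    tail: int = 120,
    gap_length: float = 15.0,
    params: BehaviorParams = DEFAULT_PARAMS,
    burn_in: int = 600,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Exponentially decaying traffic series plus a matched initial bridge.

    ``lam(t) = lam0 * exp(-decay * t)`` per second while the rate stays
    above 0.01 ants/s, followed by ``tail`` seconds of zero traffic — the
    field protocol keeps observing after the trail has been swept clear,
    until the bridge has dismantled.  The initial bridge size is the
    simulator's stationary mean under constant ``lam0`` (seeded burn-in,
    mean size over the last third, rounded).  ``lam0 = 0`` flags an empty
    experiment.
    """
    if decay <= 0:
        raise ValueError("decay constant must be positive")
    if lam0 < 0:
        raise ValueError("lam0 must be >= 0")
    if lam0 == 0:
        raise ValueError("lam0 = 0: empty experiment (no traffic to interrupt)")
    # decay phase lasts until the rate falls below 0.01 ants/s
    horizon = max(1, int(math.ceil(math.log(lam0 / 0.01) / decay)))
    t = np.arange(horizon + max(0, int(tail)))
    series = np.where(t < horizon, lam0 * np.exp(-decay * t), 0.0)

    res = simulate(TrafficProtocol(kind="constant", lam=lam0),
                   gap_length=gap_length, duration=burn_in, params=params,
                   seed=seed)
    initial_n = int(round(float(res.bridge_size[2 * burn_in // 3:].mean())))
    return series, initial_n


def generate_caste_table(
    context: str = "bridge",
    proportions: dict[str, float] | None = None,
    n: int | None = None,
    exact: bool = False,
    seed: int = 0,
) -> CasteCounts:
    """Caste counts for one structure context.

    With ``exact=True`` the printed field counts for ``context`` are
    returned verbatim; otherwise counts are a multinomial draw of size
    ``n`` from ``proportions`` (defaulting to the printed proportions of
    the context).
    """
    if exact:
        if context not in PRINTED_CASTE_COUNTS:
            raise ValueError(f"no printed counts for context {context!r}")
        return CasteCounts(context, dict(PRINTED_CASTE_COUNTS[context]))
    if proportions is None:
        printed = PRINTED_CASTE_COUNTS[context]
        total = sum(printed.values())
        proportions = {k: v / total for k, v in printed.items()}
    p = np.array(list(proportions.values()), dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if n is None:
        n = sum(PRINTED_CASTE_COUNTS.get(context, {"": 1000}).values())
    rng = np.random.default_rng(seed)
    draw = rng.multinomial(int(n), p)
    return CasteCounts(context, dict(zip(proportions.keys(), draw.tolist())))


def _filtered_noise_texture(size: int, smooth_sigma: float,
                            rng: np.random.Generator) -> np.ndarray:
    from scipy import ndimage
    tex = rng.standard_normal((size, size))
    tex = ndimage.gaussian_filter(tex, smooth_sigma, mode="wrap")
    tex -= tex.min()
    rngv = tex.max()
    return tex / rngv if rngv > 0 else tex


def generate_translating_frames(
    n_frames: int = 50,
    size: int = 256,
    speed: float | Sequence[float] = 1.0,
    axis_angle_deg: float = 0.0,
    fps: float = 25.0,
    oscillation_period: float | None = None,
    texture_sigma: float = 8.0,
    noise_level: float = 0.0,
    seed: int = 0,
) -> FrameWindow:
    """Filtered-noise texture translating along a configurable axis.

    ``speed`` (px/frame) may be a constant, an explicit per-frame profile,
    or — with ``oscillation_period`` set (s) — a raised sine
    ``speed * (1 + sin) / 2`` oscillating at that period.  Translation is
    applied by exact periodic (Fourier) shifting of the texture, so a
    constant speed of ``d`` px/frame is a ground-truth displacement of
    exactly ``d`` for the optical-flow pipeline.  Optional additive pixel
    noise of standard deviation ``noise_level``.
    """
    rng = np.random.default_rng(seed)
    tex = _filtered_noise_texture(size, texture_sigma, rng)

    if np.isscalar(speed):
        if oscillation_period is not None:
            t = np.arange(n_frames) / fps
            prof = float(speed) * 0.5 * (
                1.0 + np.sin(2.0 * np.pi * t / oscillation_period))
        else:
            prof = np.full(n_frames, float(speed))
    else:
        prof = np.asarray(speed, dtype=float)
        if len(prof) < n_frames:
            raise ValueError("speed profile shorter than n_frames")
    if np.any(~np.isfinite(prof)):
        raise ValueError("speed profile must be finite")

    ang = math.radians(axis_angle_deg)
    ux, uy = math.cos(ang), math.sin(ang)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    tex_f = np.fft.fft2(tex)

    frames = np.empty((n_frames, size, size))
    shift = 0.0
    for i in range(n_frames):
        if i > 0:
            shift += prof[i - 1]
        dx, dy = shift * ux, shift * uy
        phase = np.exp(-2j * np.pi * (fx * dx + fy * dy))
        frames[i] = np.real(np.fft.ifft2(tex_f * phase))
    if noise_level > 0:
        frames += noise_level * rng.standard_normal(frames.shape)
    return FrameWindow(frames=frames, frame_rate=fps)
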