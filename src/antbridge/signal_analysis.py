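"""Time-series analyses of trail traffic.

Covers the periodicity analysis of traffic traces (running average,
Lomb-Scargle periodogram over 1/30-1 Hz with a power-weighted dominant
frequency), the lagged block cross-correlation between trail traffic and
bridge size used in the perturbation-replay analysis, and the printed-count
caste-proportion arithmetic.

The Lomb-Scargle power is computed with :func:`scipy.signal.lombscargle`
(floating-mean model, standard normalization, so power lies in [0, 1]).
Peak significance uses the Baluev aliasing-free upper bound on the
false-alarm probability of the maximum: for standard normalization with
``N`` samples,

    FAP_single(z) = (1 - z)^((N-3)/2)
    tau(z)        = W * (1 - z)^((N-4)/2) * sqrt(z),   W = f_max * sqrt(4 pi var(t))
    FAP(z)        = 1 - (1 - FAP_single(z)) * exp(-tau(z))

Local maxima of the periodogram with FAP below the threshold (default
0.05) count as significant peaks; the dominant frequency is their
power-weighted mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

__all__ = [
    "TrafficTrace",
    "Periodogram",
    "LagCorrelation",
    "CasteCounts",
    "running_average",
    "lomb_scargle",
    "false_alarm_probability",
    "dominant_period_distribution",
    "block_cross_correlation",
    "replicate_block_cross_correlation",
    "caste_proportions",
]


@dataclass
class TrafficTrace:
    """A (possibly irregularly sampled) traffic time series."""
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must be 1-D and equal length")
        if self.timestamps.size == 0:
            raise ValueError("trace is empty")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.timestamps, "value": self.values})


@dataclass
class Periodogram:
    frequencies: np.ndarray                  # Hz
    power: np.ndarray                        # standard-normalized, in [0, 1]
    fap: np.ndarray                          # Baluev FAP per frequency bin
    significant_peaks: pd.DataFrame          # columns: frequency, power, fap
    dominant_frequency: float | None         # Hz; power-weighted mean of peaks
    dominant_period: float | None            # s; reciprocal of the above

    @property
    def has_significant_peak(self) -> bool:
        return self.dominant_frequency is not None


@dataclass
class LagCorrelation:
    lags: np.ndarray                 # seconds
    correlation: np.ndarray          # Pearson r per lag (NaN where undefined)
    max_r: float
    argmax_lag: float


@dataclass
class CasteCounts:
    """Worker counts per size class in one structure context."""
    context: str                      # bridge | bivouac | raid
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for caste, c in self.counts.items():
            if int(c) != c or c < 0:
                raise ValueError(f"count for {caste!r} must be a non-negative integer")
        self.counts = {k: int(v) for k, v in self.counts.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def running_average(trace: TrafficTrace, window: float) -> TrafficTrace:
    """Centered moving mean with a time window in seconds.

    Each output sample averages all samples within ``window/2`` seconds of
    its timestamp; at the edges the available partial window is used.
    Robust to irregular sampling.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = trace.timestamps
    v = trace.values
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return TrafficTrace(t.copy(), out)


def false_alarm_probability(
    z: np.ndarray | float,
    n_samples: int,
    t_span_var: float,
    fmax: float,
) -> np.ndarray | float:
    """Baluev-style false-alarm probability for standard-normalized power."""
    from scipy.special import gammaln

    z = np.clip(np.asarray(z, dtype=float), 0.0, 1.0 - 1e-15)
    nh = n_samples - 1.0   # dof of the constant-mean model
    nk = n_samples - 3.0   # dof of the sinusoid-plus-mean model
    fap_single = (1.0 - z) ** (0.5 * nk)
    w = fmax * np.sqrt(4.0 * np.pi * t_span_var)
    g = np.sqrt(2.0 / nh) * np.exp(gammaln((nh + 1.0) / 2.0) - gammaln(nh / 2.0))
    tau = g * w * (1.0 - z) ** (0.5 * (nk - 1.0)) * np.sqrt(0.5 * nh * z)
    fap = 1.0 - (1.0 - fap_single) * np.exp(-tau)
    return fap if fap.ndim else float(fap)


def lomb_scargle(
    trace: TrafficTrace,
    fmin: float = 1.0 / 30.0,
    fmax: float = 1.0,
    oversample: int = 5,
    fap_threshold: float = 0.05,
) -> Periodogram:
    """Lomb-Scargle periodogram with significant-peak extraction.

    The frequency grid spans [``fmin``, ``fmax``] at ``oversample`` times
    the natural resolution ``1/T``.  Local maxima with false-alarm
    probability below ``fap_threshold`` are flagged; the dominant
    frequency is their mean weighted by spectral power, and the dominant
    period its reciprocal.  If no peak is significant the dominant fields
    are ``None`` and a warning is issued.
    """
    t = trace.timestamps
    y = trace.values
    n = len(y)
    if n < 16:
        raise ValueError("need at least 16 samples for a periodogram")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("trace spans zero time")
    df = 1.0 / (oversample * span)
    freqs = np.arange(fmin, fmax + df / 2.0, df)
    power = lombscargle(t, y, 2.0 * np.pi * freqs,
                        normalize="normalize", floating_mean=True)
    power = np.clip(power, 0.0, 1.0)
    fap = np.asarray(false_alarm_probability(power, n, np.var(t), fmax))

    interior = np.zeros(len(freqs), dtype=bool)
    if len(freqs) >= 3:
        interior[1:-1] = (power[1:-1] > power[:-2]) & (power[1:-1] >= power[2:])
    peak_mask = interior & (fap < fap_threshold)
    peaks = pd.DataFrame({
        "frequency": freqs[peak_mask],
        "power": power[peak_mask],
        "fap": fap[peak_mask],
    })

    if len(peaks):
        w = peaks["power"].to_numpy()
        f_dom = float(np.sum(peaks["frequency"].to_numpy() * w) / np.sum(w))
        p_dom = 1.0 / f_dom
    else:
        warnings.warn("no significant periodogram peak", RuntimeWarning)
        f_dom = p_dom = None
    return Periodogram(freqs, power, fap, peaks, f_dom, p_dom)


def dominant_period_distribution(
    traces: Iterable[TrafficTrace],
    fmin: float = 1.0 / 30.0,
    fmax: float = 1.0,
    oversample: int = 5,
    fap_threshold: float = 0.05,
) -> dict:
    """Per-trace dominant frequencies and their median across traces.

    Traces without a significant peak are excluded from the median and
    counted in the report.
    """
    freqs = []
    n_excluded = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for trace in traces:
            pg = lomb_scargle(trace, fmin, fmax, oversample, fap_threshold)
            if pg.has_significant_peak:
                freqs.append(pg.dominant_frequency)
            else:
                n_excluded += 1
    if not freqs:
        raise ValueError("no trace has a significant periodogram peak")
    freqs = np.asarray(freqs)
    return {
        "dominant_frequencies": freqs,
        "dominant_periods": 1.0 / freqs,
        "median_frequency": float(np.median(freqs)),
        "median_period": float(1.0 / np.median(freqs)),
        "n_traces": len(freqs) + n_excluded,
        "n_excluded": n_excluded,
    }


def _block_means(x: np.ndarray, block: int) -> np.ndarray:
    nb = len(x) // block
    if nb == 0:
        return np.empty(0)
    return x[: nb * block].reshape(nb, block).mean(axis=1)


def block_cross_correlation(
    traffic: Sequence[float] | np.ndarray,
    bridge_size: Sequence[float] | np.ndarray,
    block: int = 10,
    lags: Sequence[int] | None = None,
) -> LagCorrelation:
    """Pearson correlation of block-aggregated traffic vs bridge size at lags.

    A lag of ``L`` seconds correlates the traffic at time ``t - L`` with
    the bridge size at ``t`` (the bridge responds to earlier traffic).
    Both series are shifted, then aggregated into consecutive ``block``-s
    means; blocks overhanging the series end are dropped.  A lag with
    fewer than 3 overlapping blocks (or a constant series) is reported as
    NaN.
    """
    x = np.asarray(traffic, dtype=float)
    y = np.asarray(bridge_size, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and cover the same interval")
    if len(x) < 3 * block:
        raise ValueError(f"series must be at least {3 * block} s long")
    if lags is None:
        lags = np.arange(0, 101, 10)
    lags = np.asarray(lags, dtype=int)

    rs = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        if lag >= len(x):
            continue
        xb = _block_means(x[: len(x) - lag], block)
        yb = _block_means(y[lag:], block)
        if len(xb) < 3 or np.std(xb) == 0 or np.std(yb) == 0:
            continue
        rs[i] = float(np.corrcoef(xb, yb)[0, 1])
    if np.all(np.isnan(rs)):
        raise ValueError("correlation undefined at every lag")
    imax = int(np.nanargmax(rs))
    return LagCorrelation(lags.astype(float), rs, float(rs[imax]),
                          float(lags[imax]))


def replicate_block_cross_correlation(
    traffic: Sequence[float] | np.ndarray,
    bridge_sizes: np.ndarray,
    block: int = 10,
    lags: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Mean r and 95% confidence band per lag over replicate bridge series.

    ``bridge_sizes`` has shape ``(reps, T)``; the same traffic series is
    correlated against each replicate.
    """
    bridge_sizes = np.atleast_2d(np.asarray(bridge_sizes, dtype=float))
    rows = []
    for rep in range(bridge_sizes.shape[0]):
        lc = block_cross_correlation(traffic, bridge_sizes[rep], block, lags)
        rows.append(lc.correlation)
    rmat = np.vstack(rows)
    lags_arr = lc.lags
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(rmat, axis=0)
        sd = np.nanstd(rmat, axis=0, ddof=1) if rmat.shape[0] > 1 else np.zeros_like(mean_r)
    n_ok = np.sum(~np.isnan(rmat), axis=0)
    half = 1.96 * sd / np.sqrt(np.maximum(n_ok, 1))
    return pd.DataFrame({
        "lag": lags_arr,
        "mean_r": mean_r,
        "ci_low": mean_r - half,
        "ci_high": mean_r + half,
        "n": n_ok,
    })


def caste_proportions(counts: CasteCounts | Mapping[str, int]) -> dict[str, float]:
    """Percentage of each caste, rounded to one decimal for reporting."""
    if isinstance(counts, CasteCounts):
        d = counts.counts
    else:
        d = {k: int(v) for k, v in counts.items()}
    total = sum(d.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return {caste: round(100.0 * c / total, 1) for caste, c in d.items()}
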