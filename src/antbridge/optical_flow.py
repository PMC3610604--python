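"""Derivative-based optical-flow estimate of relative trail traffic.

From a window of greyscale frames centred on a foraging trail, the trail
axis is found by fitting a straight line through the pixels weighted by
their temporal intensity variance.  For each successive frame pair a
dense velocity field is estimated from image derivatives: the temporal
derivative is the frame difference, the two spatial derivatives come from
large (45x45 by default) separable Sobel-family kernels, the pairwise
derivative products are smoothed with a wide Gaussian and combined into a
per-pixel velocity by local least squares (the classic Lucas-Kanade
construction from exactly those smoothed products).  Projecting the
velocity vectors on the trail axis and summing the absolute projections
yields a relative traffic index per frame pair — relative only, since
absolute calibration is not possible from uncontrolled footage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import comb

from .signal_analysis import TrafficTrace

__all__ = [
    "FrameWindow",
    "TrailAxis",
    "VelocityField",
    "sobel_kernel_1d",
    "estimate_trail_axis",
    "velocity_field",
    "traffic_index",
    "trace_from_frames",
]


@dataclass
class FrameWindow:
    """A stack of same-shaped greyscale frames with a frame rate."""
    frames: np.ndarray       # (n_frames, H, W), float intensities
    frame_rate: float        # Hz

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if np.any(~np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class TrailAxis:
    direction: np.ndarray    # unit 2-vector (dx, dy) in pixel coordinates
    offset: np.ndarray       # a point on the line (x, y)

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if nrm == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = self.direction / nrm
        self.offset = np.asarray(self.offset, dtype=float)


@dataclass
class VelocityField:
    vx: np.ndarray           # pixels/frame, x = column direction
    vy: np.ndarray           # pixels/frame, y = row direction

    def __post_init__(self) -> None:
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy must have the same shape")


def sobel_kernel_1d(size: int = 45) -> tuple[np.ndarray, np.ndarray]:
    """Smoothing and derivative taps of a ``size``-tap Sobel-family kernel.

    Built as the binomial extension of the 3x3 Sobel pair: the smoothing
    taps are binomial coefficients normalized to sum 1, the derivative
    taps are a central difference convolved with a shorter binomial,
    normalized to unit derivative gain (response 1 to a unit ramp).
    The 2-D kernels are the separable outer products smoothing (x)
    derivative.
    """
    if size < 3 or size % 2 == 0:
        raise ValueError("size must be an odd integer >= 3")
    smooth = comb(size - 1, np.arange(size), exact=False)
    smooth = smooth / smooth.sum()
    base = comb(size - 3, np.arange(size - 2), exact=False)
    deriv = np.convolve(base, [1.0, 0.0, -1.0])
    # unit gain on f(x) = x: sum_k deriv[k] * (center - k) == 1
    offsets = (size - 1) / 2.0 - np.arange(size)
    deriv = deriv / np.sum(deriv * offsets)
    return smooth, deriv


def estimate_trail_axis(window: FrameWindow) -> TrailAxis:
    """Fit the trail axis from per-pixel temporal intensity variance.

    The variance of each pixel across frames weights its coordinates; the
    axis is the leading principal direction of the weighted coordinate
    cloud (a total-least-squares line, valid for any orientation) through
    the weighted centroid.
    """
    if len(window) < 10:
        raise ValueError("need at least 10 frames to estimate the trail axis")
    w = np.var(window.frames, axis=0)
    total = w.sum()
    if total <= 0:
        raise ValueError("static scene: temporal variance is zero everywhere")
    h, wid = w.shape
    yy, xx = np.mgrid[0:h, 0:wid]
    wx = float(np.sum(w * xx) / total)
    wy = float(np.sum(w * yy) / total)
    dx = xx - wx
    dy = yy - wy
    cxx = float(np.sum(w * dx * dx) / total)
    cyy = float(np.sum(w * dy * dy) / total)
    cxy = float(np.sum(w * dx * dy) / total)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    vals, vecs = np.linalg.eigh(cov)
    direction = vecs[:, np.argmax(vals)]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction  # canonical orientation; index is sign-blind
    return TrailAxis(direction=direction, offset=np.array([wx, wy]))


def velocity_field(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    sobel_size: int = 45,
    gaussian_sigma: float = 16.0,
    gaussian_support: int = 100,
    regularization: float = 1e-4,
) -> VelocityField:
    """Estimate per-pixel motion (pixels/frame) between two frames.

    Temporal derivative: ``frame_b - frame_a``.  Spatial derivatives: the
    mean frame filtered with separable ``sobel_size``-tap Sobel-family
    kernels.  The five derivative products are smoothed with a Gaussian
    (sigma ``gaussian_sigma`` px, kernel support ``gaussian_support`` px)
    and the smoothed normal equations are solved per pixel, with a small
    Tikhonov term guarding near-singular neighbourhoods (untextured or
    aperture-limited regions).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be 2-D arrays of the same shape")

    it = b - a
    mean = 0.5 * (a + b)
    smooth, deriv = sobel_kernel_1d(sobel_size)
    # x = columns (axis 1), y = rows (axis 0)
    ix = ndimage.convolve1d(ndimage.convolve1d(mean, deriv, axis=1, mode="nearest"),
                            smooth, axis=0, mode="nearest")
    iy = ndimage.convolve1d(ndimage.convolve1d(mean, deriv, axis=0, mode="nearest"),
                            smooth, axis=1, mode="nearest")

    truncate = (gaussian_support / 2.0 - 0.5) / gaussian_sigma
    def g(img: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(img, gaussian_sigma, truncate=truncate,
                                       mode="nearest")

    jxx = g(ix * ix)
    jyy = g(iy * iy)
    jxy = g(ix * iy)
    jxt = g(ix * it)
    jyt = g(iy * it)

    eps = regularization * float(np.mean(jxx + jyy)) + 1e-30
    axx = jxx + eps
    ayy = jyy + eps
    det = axx * ayy - jxy * jxy
    vx = (-jxt * ayy + jyt * jxy) / det
    vy = (-jyt * axx + jxt * jxy) / det
    return VelocityField(vx=vx, vy=vy)


def traffic_index(field: VelocityField, axis: TrailAxis) -> float:
    """Sum over pixels of the absolute velocity projection on the axis.

    A relative measure of traffic; invariant under reversal of the axis
    direction.
    """
    proj = field.vx * axis.direction[0] + field.vy * axis.direction[1]
    return float(np.sum(np.abs(proj)))


def trace_from_frames(
    window: FrameWindow,
    axis: TrailAxis | None = None,
    sobel_size: int = 45,
    gaussian_sigma: float = 16.0,
    gaussian_support: int = 100,
) -> TrafficTrace:
    """Relative traffic index per successive frame pair as a TrafficTrace.

    Timestamps sit at the frame-pair midpoints.  If no axis is supplied
    it is estimated from the window itself; a static window yields an
    all-zero trace along the x axis.
    """
    if len(window) < 2:
        raise ValueError("need at least 2 frames")
    if axis is None:
        try:
            axis = estimate_trail_axis(window)
        except ValueError:
            axis = TrailAxis(direction=np.array([1.0, 0.0]),
                             offset=np.array([0.0, 0.0]))
    frames = window.frames
    n_pairs = len(window) - 1
    values = np.empty(n_pairs)
    for i in range(n_pairs):
        vf = velocity_field(frames[i], frames[i + 1], sobel_size,
                            gaussian_sigma, gaussian_support)
        values[i] = traffic_index(vf, axis)
    times = (np.arange(n_pairs) + 0.5) / window.frame_rate
    return TrafficTrace(times, values)
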