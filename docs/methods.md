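# Methods

## Model and assumptions

The simulator is a pseudo-spatial, discrete-time (1 s) individual-based
model of living-bridge self-assembly. It tracks no geometry beyond the gap
length: the state is the set of current bridge members, each carrying the
packing density at the moment it joined, the traffic share derived from it,
and a memory of recent per-second crossing counts.

Per step, with instantaneous arrival rate λ(t):

1. **Arrivals.** `k ~ Poisson(λ(t))` ants reach the gap and are processed
   sequentially. Each joins with probability
   `p_join = α + (1−α)/(1 + (1/β)·exp(γ·λ(t) + θ·D))`, where the packing
   density `D` is updated after every join (so an arrival sees the ants
   that joined just before it); otherwise it crosses. The traffic
   covariate is the protocol's instantaneous rate, not the realized draw —
   the behavioural covariate is trail traffic intensity, of which the
   per-second draw is a noisy realization.
2. **Departures.** All members decide simultaneously, using the crossing
   counts of the *preceding* m seconds: member *i* leaves with probability
   `min(1, 1/(ρ·exp(σ·f_i)))`, where `f_i = s(D_join,i) × mean(last m
   crossing counts)`. Simultaneity matches the absence of any ordering
   information for departures; joiners of the current step are exposed to
   the same decision.
3. **Memory update.** The step's crossing count (arrivals that did not
   join; leavers are not re-counted) is appended to the memory. Before m
   counts exist the buffer is padded with the first observed value. All
   members share the same global crossing history — a new joiner
   inherits it — so the per-ant distinction lives entirely in the share
   factor.

Assumptions worth making explicit: no within-second event timing; no
spatial structure (the share function is the only proxy for position); no
caste-specific parameters; ants never rejoin with memory of a previous
stay.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| α | lower asymptote of join probability | – | 0.02 |
| β | join-sigmoid scale | – | 144.5 |
| γ | join-sigmoid slope in trail traffic | per ants/s | 3.258 |
| θ | join-sigmoid slope in packing density | per ants/mm | 12.97 |
| ρ | residence-time scale (zero-flow residence) | s | 1.959 |
| σ | residence-time exponent | per ants/s | 2.789 |
| φ, ψ, ω | traffic-share shape | – | −0.52, 3, 2 |
| m | flow-memory length | s | 5 |
| gap length | bridge span | mm | 15 |
| max rate | square-wave high phase | ants/s | 3 |

The defaults are the field-fitted values for *E. burchellii*; ln 2/σ ≈
0.25 ants/s is the local-flow increment that doubles residence time.

Two of the three rule functions are reconstructions: the published
equations are not machine-readable in the available source, so the join
sigmoid and the share function use the forms above — chosen to be
sigmoidal and decreasing in both covariates, to use every printed
parameter, and to give sensible limits (p → α under heavy traffic,
p ≈ 0.99 on an empty quiet gap; s clamped to a proportion). Both forms are
kept behind `BehaviorParams` so alternatives can be swapped in. The
leaving probability is the clamped reciprocal of the residence curve.

## Simulation protocols

* **Poisson sweep** — λ from 0.1 to 4 ants/s in 0.05 steps, 600 s per run,
  1000 replicates per λ, 15 mm gap; summary is the non-empty bridge time
  ratio (fraction of seconds with ≥ 1 member).
* **Oscillation sweep** — square-wave traffic, high phase at the maximum
  rate for the first half-period, low phase at `max_rate·(1−intensity)`;
  sampled at integer seconds (`t mod P < P/2`), so odd periods get
  ⌈P/2⌉ high seconds and period 1 degenerates to constant flow. Each run
  starts empty and lasts 100 oscillation periods.
* **Perturbation replay** — the bridge is seeded with n ants assumed to
  have joined sequentially onto an empty gap (member *i* at density
  *i*/L), each with memory filled by the pre-perturbation traffic level;
  λ(t) then follows the recorded series second by second.

Replicate *r* of any run derives its RNG stream from
`SeedSequence([master_seed, r])`; every protocol is bit-reproducible per
engine. The readable Python engine and the numba kernel implement
identical rules but draw from different generators, so they agree
statistically, not bitwise (the suite checks both conservation per step
and cross-engine agreement of mean occupancy).

## Where the reconstruction bends the results

Two study-scale behaviours depend on the unrecoverable functional forms,
and the defaults land close to — but not on — the published optima. Both
are asserted at their robust, qualitative level in the test suite and
reported numerically by `scripts/acceptance.py`; neither tolerance was
adjusted to mask the gap.

* **Stability vs. traffic intensity.** With the default sigmoid the join
  influx λ·p_join(λ, 0) peaks near λ ≈ 1.7 ants/s and declines, so the
  non-empty ratio rises steeply (sigmoidally, maximum slope near
  λ ≈ 0.75) but dips by ≈ 0.02 beyond λ ≈ 2. Strict monotonicity of the
  full sweep therefore fails even at 1000 replicates. The alternative
  reading of the sigmoid (β multiplying the exponential) restores
  monotonicity but flattens the join probability into [0.020, 0.027],
  which would make the sigmoid unfittable from event records and is not
  adopted.
* **Oscillation-period optimum.** The stability optimum sits in the
  3–5 s band at every oscillation intensity, but periods 3 and 5 are
  statistically tied at full depth (Δratio < 0.005 at 3000 replicates):
  the integer-sampled square wave gives odd periods an elevated duty
  cycle, and the 100-period protocol makes short-period runs shorter, so
  formation transients weigh more. The intensity-averaged argmax lands on
  5 s. The robust findings — an interior short-period optimum, sharp
  decline beyond ~7 s, and monotone destabilization with oscillation
  intensity — hold for every seed and gap length tested (5–30 mm).

## Signal analysis

Lomb–Scargle periodograms use the floating-mean model with standard
normalization on a grid spanning 1/30–1 Hz at 5× the natural resolution
1/T. Peaks are local maxima whose Baluev false-alarm probability (the
aliasing-free upper bound for the maximum of a standard-normalized
periodogram) is below 0.05; the dominant frequency is the power-weighted
mean of significant peak frequencies. On white noise, ≈ 4% of 100 seeded
traces show a significant peak at the 5% threshold.

Block cross-correlation aggregates both series into consecutive 10-s block
means (overhanging blocks dropped); lag L correlates traffic at t−L with
bridge size at t, so positive lags mean the bridge trails traffic. Lags
with fewer than 3 overlapping blocks are undefined. Over replicates the
mean r and a normal-approximation 95% band are reported. Note the model
bridge intrinsically trails traffic by roughly m/2 seconds; with 10-s
blocks and a zero-traffic observation tail after the decay (as in the
sweeping experiments) the maximum lands at lag 0.

## Optical flow

Frames are floating-point intensities in [0, 1]; no histogram
equalization. The trail axis is the leading principal direction of pixel
coordinates weighted by temporal intensity variance (a total-least-squares
line, valid at any orientation). Spatial derivatives use separable
45-tap Sobel-family kernels (binomial smoothing ⊗ binomial-smoothed
central difference, normalized to unit ramp gain); the temporal derivative
is the raw frame difference. The five derivative products are smoothed
with a Gaussian of σ = 16 px on a 100-px support and combined per pixel by
regularized 2×2 least squares (Lucas–Kanade normal equations; Tikhonov
term 10⁻⁴ of the mean gradient energy guards untextured neighbourhoods).
The traffic index sums |v·axis| over pixels — a relative measure,
insensitive to axis orientation, not calibrated to absolute flow. On
synthetic 1 px/frame translations the interior mean velocity is recovered
within ≈ 17%; a residual positive bias comes from the asymmetric temporal
derivative.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analyses need:
removal-experiment tables come from the simulator itself (so recovery
tests are exact by construction), with per-episode traffic drawn uniformly
from 0.25–4 ants/s to span the covariate space; trail traces carry a
sine or square oscillation with Gaussian or Poisson noise at 25 Hz;
perturbation series decay exponentially (default 0.05 s⁻¹, inside the
0.01–0.1 s⁻¹ range implied by observed dismantling times) followed by a
zero-traffic observation tail, with the initial bridge set to the
simulator's stationary mean after a 600 s burn-in; frame stacks translate
a Gaussian-filtered noise texture by exact Fourier shifts.

They do **not** emulate: camera artifacts, lighting variation, bridge
width, caste-dependent movement, observer mislabeling, or the heavy-tailed
burstiness of real trail traffic (noise is Gaussian/Poisson). Passing
recovery tests therefore demonstrates internal consistency of the
pipeline, not field-readiness. Residence tables from full simulations are
right-censored at the episode length, exactly as field observations were
capped — high-flow bins underestimate the residence curve, and fits meant
to recover (ρ, σ) should use the direct-noise generator or censoring-aware
methods.

## Numerical choices and degenerate inputs

Exponentials are clipped at exp(700) to avoid overflow where the sigmoid
or residence curve is saturated anyway. The join fit optimizes log β with
multi-start (8 seeded starts) bounded least squares, objective tolerance
1e-8; all-identical outcomes raise instead of returning a boundary
solution. The residence fit seeds nonlinear least squares from a
log-linear fit; constant flows raise (σ unidentifiable). Share calibration
searches an 11³ grid (φ ∈ [−2,0], ψ ∈ [0.5,5], ω ∈ [0.5,4]) with common
random numbers across parameter points, then refines by Nelder–Mead; a
flat objective (e.g. an all-zero target under zero traffic) warns and
flags the result degenerate. The calibration reports both the mean squared
difference (ants²) and its square root, since the published benchmark's
units are ambiguous. Zero-rate seconds draw no arrivals; an empty memory
buffer yields zero local flow (leaving probability 1/ρ).

## Problem sizes

The suite and the acceptance script run the sweeps at the sizes chosen for
routine desk use: 200 replicates per oscillation-sweep cell (the published
protocol's 1000 is available via `reps=`), 1000 replicates per λ for the
Poisson sweep, 5000-arrival join-fit recovery, 30 × 1000-record residence
recovery, 100-seed false-alarm calibration, and 240-frame optical-flow
round trips at 128² pixels. At these sizes replicate noise on a non-empty
ratio is below 0.01, small against every asserted margin.

## Known limitations

* The two reconstructed rule functions are plausible but not verbatim;
  conclusions that hinge on their curvature (exact optimum location,
  high-λ monotonicity) carry that uncertainty.
* The model is caste-agnostic; caste tables are bookkeeping only.
* Traffic shares are frozen at join time — members do not renegotiate
  position as the bridge grows or shrinks.
* The optical-flow module assumes a single dominant motion axis and
  texture-rich imagery; it yields a relative index only.
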