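# antbridge

Army ants (*Eciton burchellii*) span gaps on their foraging trails by
interlinking their bodies into living bridges. These structures are at once
stable — they persist through the second-scale traffic oscillations typical
of ant trails — and responsive, dismantling within seconds when traffic is
interrupted. `antbridge` implements a data-driven, pseudo-spatial
individual-based model of bridge self-assembly and the analysis pipeline
built around it, for behavioural ecologists and collective-behaviour
modellers who want to simulate, fit and probe this kind of self-assembled
architecture without field recordings.

## The model

Time advances in 1-second steps. Each second, a Poisson number of ants
(rate λ, ants/s) reaches a gap of length *L* mm currently bridged by *N*
ants (packing density *D = N/L*, ants/mm). Each arrival joins the bridge
with probability

```
p_join(λ, D) = α + (1 − α) / (1 + (1/β) · exp(γ·λ + θ·D))
```

a bivariate sigmoid decreasing in trail traffic and packing density with
lower asymptote α (fitted values α = 0.02, β = 144.5, γ = 3.258 per ants/s,
θ = 12.97 per ants/mm); otherwise it crosses. A member that joined at
packing density *D*ⱼ intercepts a share

```
s(Dⱼ) = min(1, ψ · exp(φ · Dⱼ^ω))          (φ = −0.52, ψ = 3, ω = 2)
```

of the bridge traffic; its local flow is that share times the mean
per-second crossing count over the last *m* = 5 seconds. Residence time
grows exponentially with local flow, T(f) = ρ·exp(σ·f) (ρ = 1.959 s,
σ = 2.789 per ants/s — an extra 0.25 ants/s doubles the residence time),
so each member leaves with per-second probability min(1, 1/T(f)).

Around the model the package provides:

- **`antbridge.model_core`** — the rule functions and their fitting:
  least-squares join-sigmoid fit to success/failure event records,
  nonlinear least-squares residence fit, and simulation-based calibration
  of the share parameters (φ, ψ, ω).
- **`antbridge.simulator`** — the stochastic engine (a readable Python
  engine plus a numba kernel for sweeps) and the three protocols:
  constant-Poisson stability sweeps, square-wave oscillation sweeps
  (100 oscillation periods per run), and perturbation replay into a
  pre-seeded bridge.
- **`antbridge.signal_analysis`** — running average, Lomb–Scargle
  periodograms over 1/30–1 Hz with Baluev false-alarm-calibrated peaks and
  a power-weighted dominant frequency, lagged 10-s-block cross-correlation
  of traffic vs bridge size, and caste-count arithmetic.
- **`antbridge.optical_flow`** — relative traffic quantification from
  greyscale frame stacks: variance-weighted trail-axis fit, 45×45
  Sobel-family derivatives smoothed by a 100×100-support Gaussian,
  Lucas–Kanade-style velocity fields, absolute projection onto the trail
  axis.
- **`antbridge.synthetic`** — seeded generators for every input: removal
  experiments simulated with known ground truth, oscillating trail traces,
  exponentially decaying perturbation series, caste tables, and
  translating-texture frame stacks.
- **`antbridge` CLI** — thin subcommands (`simulate`, `sweep-poisson`,
  `sweep-oscillation`, `replay`, `fit-join`, `fit-residence`, `calibrate`,
  `periodogram`, `xcorr`, `castes`, `flow-trace`, `synth …`, `pipeline`)
  that read/write CSV + YAML and drop a JSON manifest beside every output.

## Worked example

```python
import numpy as np
from antbridge import TrafficProtocol, simulate, lomb_scargle
from antbridge.synthetic import generate_trail_trace, generate_perturbation_trace
from antbridge.simulator import replay_perturbation
from antbridge.signal_analysis import replicate_block_cross_correlation

# a bridge under steady traffic of 1.5 ants/s across a 15 mm gap
res = simulate(TrafficProtocol(kind="constant", lam=1.5), gap_length=15.0,
               duration=600, seed=42)
print(f"non-empty ratio: {res.non_empty_ratio:.3f}")
print(f"mean bridge size: {res.bridge_size.mean():.2f} ants")

# periodicity of a synthetic trail-traffic recording
trace = generate_trail_trace(period=3.4, depth=0.5, noise_level=0.1, seed=42)
pg = lomb_scargle(trace)
print(f"dominant period: {pg.dominant_period:.3f} s ({pg.dominant_frequency:.3f} Hz)")

# replay a sudden traffic interruption into a stationary bridge
series, n0 = generate_perturbation_trace(lam0=2.0, decay=0.05, seed=42)
sizes = replay_perturbation(series, n0, reps=200, seed=42)
xc = replicate_block_cross_correlation(series, sizes)
best = xc.loc[xc.mean_r.idxmax()]
print(f"replay: initial bridge {n0} ants, max mean r = {best.mean_r:.3f} at lag {best.lag:.0f} s")
```

prints

```
non-empty ratio: 0.993
mean bridge size: 4.46 ants
dominant period: 3.407 s (0.294 Hz)
replay: initial bridge 7 ants, max mean r = 0.957 at lag 0 s
```

The bridge is occupied 99.3% of the time at moderate steady traffic; the
periodogram recovers the injected 3.4-s traffic oscillation; and after a
sudden traffic interruption the bridge size tracks the collapsing traffic
with maximum correlation at zero lag — the stability/responsiveness duality
the model is built to capture.

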