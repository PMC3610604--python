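"""Numba-jitted hot loop of the bridge simulator.

The sweeps of the model (79 traffic intensities x 1000 replicates x 600 s,
oscillation grids of 100-period runs) execute tens of millions of
one-second steps; this kernel runs them at compiled speed.  It implements
exactly the same per-step rules as the readable reference engine in
:mod:`antbridge.simulator`:

1. draw arrivals ~ Poisson(rate); each arrival joins with the join
   sigmoid evaluated at the instantaneous protocol rate and the *current*
   packing density (updated after every join), otherwise it crosses;
2. evaluate leaving simultaneously for all members from the crossing
   counts of the preceding ``m`` seconds (shared buffer — every member's
   memory holds the same global per-second crossing counts, scaled by its
   individual traffic share);
3. append this step's crossing count (joiners excluded) to the buffer.

The memory buffer is padded with the first observed crossing count until
``m`` values exist; a replayed perturbation run starts with the buffer
filled with the pre-perturbation traffic level.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CAP = 8192  # hard cap on simultaneous bridge members; never approached in practice


@njit(cache=True)
def run_kernel(rates, gap_length,
               alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
               seed, init_n, init_mem,
               out_size, out_cross, out_joins, out_leaves):
    """Simulate one replicate; per-second tallies written into out_*."""
    np.random.seed(seed)
    T = rates.shape[0]
    shares = np.empty(_CAP)
    n = 0

    mem = np.zeros(m)
    mem_pos = 0
    mem_count = 0
    first_val = 0.0

    if init_n > 0:
        # members assumed to have joined sequentially onto an empty gap,
        # under traffic constant at init_mem for the preceding m seconds
        for i in range(min(init_n, _CAP)):
            d = i / gap_length
            s = psi * np.exp(phi * d ** omega)
            if s > 1.0:
                s = 1.0
            shares[n] = s
            n += 1
        for j in range(m):
            mem[j] = init_mem
        mem_count = m
        first_val = init_mem

    for t in range(T):
        rate = rates[t]
        n_arrivals = np.random.poisson(rate) if rate > 0.0 else 0

        joins = 0
        cross = 0
        for _ in range(n_arrivals):
            d = n / gap_length
            z = gamma * rate + theta * d
            if z > 700.0:
                z = 700.0
            p = alpha + (1.0 - alpha) / (1.0 + np.exp(z) / beta)
            if np.random.random() < p:
                if n < _CAP:
                    s = psi * np.exp(phi * d ** omega)
                    if s > 1.0:
                        s = 1.0
                    shares[n] = s
                    n += 1
                    joins += 1
            else:
                cross += 1

        # mean crossing count over the last m seconds (padded with the
        # first observed value while fewer than m have been seen)
        if mem_count == 0:
            fbar = 0.0
        elif mem_count < m:
            tot = 0.0
            for j in range(mem_count):
                tot += mem[j]
            fbar = (tot + (m - mem_count) * first_val) / m
        else:
            tot = 0.0
            for j in range(m):
                tot += mem[j]
            fbar = tot / m

        leaves = 0
        w = 0
        for i in range(n):
            zf = sigma * shares[i] * fbar
            if zf > 700.0:
                zf = 700.0
            pl = 1.0 / (rho * np.exp(zf))
            if pl > 1.0:
                pl = 1.0
            if np.random.random() < pl:
                leaves += 1
            else:
                shares[w] = shares[i]
                w += 1
        n = w

        if mem_count == 0:
            first_val = cross
        mem[mem_pos] = cross
        mem_pos = (mem_pos + 1) % m
        if mem_count < m:
            mem_count += 1

        out_size[t] = n
        out_cross[t] = cross
        out_joins[t] = joins
        out_leaves[t] = leaves


@njit(cache=True)
def ratios_over_reps(rates, gap_length,
                     alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
                     seeds):
    """Non-empty bridge time ratio for each seeded replicate."""
    R = seeds.shape[0]
    T = rates.shape[0]
    out = np.empty(R)
    size = np.empty(T, np.int64)
    cross = np.empty(T, np.int64)
    joins = np.empty(T, np.int64)
    leaves = np.empty(T, np.int64)
    for r in range(R):
        run_kernel(rates, gap_length,
                   alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
                   seeds[r], 0, 0.0, size, cross, joins, leaves)
        ne = 0
        for t in range(T):
            if size[t] > 0:
                ne += 1
        out[r] = ne / T
    return out


@njit(cache=True)
def mean_size_over_reps(rates, gap_length,
                        alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
                        seeds):
    """Per-second bridge size averaged over seeded replicates."""
    R = seeds.shape[0]
    T = rates.shape[0]
    acc = np.zeros(T)
    size = np.empty(T, np.int64)
    cross = np.empty(T, np.int64)
    joins = np.empty(T, np.int64)
    leaves = np.empty(T, np.int64)
    for r in range(R):
        run_kernel(rates, gap_length,
                   alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
                   seeds[r], 0, 0.0, size, cross, joins, leaves)
        for t in range(T):
            acc[t] += size[t]
    return acc / R


@njit(cache=True)
def replay_over_reps(rates, gap_length,
                     alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
                     seeds, init_n, init_mem):
    """Per-second bridge-size series for each replicate of a replay run."""
    R = seeds.shape[0]
    T = rates.shape[0]
    out = np.empty((R, T), np.int64)
    size = np.empty(T, np.int64)
    cross = np.empty(T, np.int64)
    joins = np.empty(T, np.int64)
    leaves = np.empty(T, np.int64)
    for r in range(R):
        run_kernel(rates, gap_length,
                   alpha, beta, gamma, theta, rho, sigma, phi, psi, omega, m,
                   seeds[r], init_n, init_mem, size, cross, joins, leaves)
        for t in range(T):
            out[r, t] = size[t]
    return out
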