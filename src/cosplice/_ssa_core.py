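"""Numba kernels for exact stochastic simulation.

All models in the package are zero- or first-order reaction networks whose
propensities switch on and off at fixed times (delay switches).  The kernels
implement the Gillespie direct method with the boundary-redraw rule: if the
sampled waiting time crosses the next switch boundary the clock advances to
the boundary and the waiting time is redrawn, which is statistically exact by
the memorylessness of the exponential distribution.

Reproducibility: each kernel seeds numba's internal RNG with the supplied
per-run seed on entry, so identical (spec, seed) pairs give bit-identical
trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_sample", "ssa_events", "ssa_bursting"]


@njit(cache=True)
def _next_switch(t: float, switch_times: np.ndarray) -> float:
    """Smallest switch time strictly greater than t (inf if none)."""
    for s in switch_times:
        if s > t:
            return s
    return np.inf


@njit(cache=True)
def _propensities(counts, reactant_idx, rates, t_on, t_off, t, a):
    a0 = 0.0
    for j in range(rates.size):
        if t_on[j] <= t < t_off[j]:
            if reactant_idx[j] < 0:
                a[j] = rates[j]
            else:
                a[j] = rates[j] * counts[reactant_idx[j]]
        else:
            a[j] = 0.0
        a0 += a[j]
    return a0


@njit(cache=True)
def ssa_sample(counts0, reactant_idx, rates, stoich, t_on, t_off,
               switch_times, t_grid, seed):
    """SSA run returning species counts sampled at the times in ``t_grid``.

    counts0      : (n_species,) int64 initial counts
    reactant_idx : (n_reactions,) int64, -1 for zero-order reactions
    rates        : (n_reactions,) float64 rate constants
    stoich       : (n_reactions, n_species) int64 state-change vectors
    t_on, t_off  : (n_reactions,) float64 active windows
    switch_times : sorted float64 array of all finite window boundaries
    t_grid       : sorted float64 sampling times; the run ends at t_grid[-1]
    """
    np.random.seed(seed)
    n_species = counts0.size
    counts = counts0.copy()
    out = np.zeros((t_grid.size, n_species), dtype=np.int64)
    a = np.zeros(rates.size)
    t = 0.0
    gi = 0
    t_end = t_grid[-1]
    while True:
        a0 = _propensities(counts, reactant_idx, rates, t_on, t_off, t, a)
        boundary = _next_switch(t, switch_times)
        if a0 <= 0.0:
            t_next = boundary
        else:
            dt = np.random.exponential(1.0 / a0)
            t_next = t + dt
            if t_next > boundary:
                # redraw after the propensity switch (memoryless)
                t = boundary
                continue
        # record grid points passed before this event fires
        while gi < t_grid.size and t_grid[gi] < t_next:
            out[gi] = counts
            gi += 1
        if t_next > t_end or gi >= t_grid.size:
            break
        t = t_next
        if a0 <= 0.0:
            continue
        # categorical draw of the firing reaction
        r = np.random.random() * a0
        acc = 0.0
        j = 0
        for j in range(a.size):
            acc += a[j]
            if r < acc:
                break
        counts += stoich[j]
    while gi < t_grid.size:
        out[gi] = counts
        gi += 1
    return out


@njit(cache=True)
def ssa_events(counts0, reactant_idx, rates, stoich, t_on, t_off,
               switch_times, t_end, seed, max_events):
    """SSA run recording (time, reaction) for every event.

    Returns (times, reaction_ids, n_events, final_counts).  Events beyond
    ``max_events`` raise via a sentinel (n_events == -1).
    """
    np.random.seed(seed)
    counts = counts0.copy()
    a = np.zeros(rates.size)
    times = np.empty(max_events)
    rids = np.empty(max_events, dtype=np.int64)
    n = 0
    t = 0.0
    while t < t_end:
        a0 = _propensities(counts, reactant_idx, rates, t_on, t_off, t, a)
        boundary = _next_switch(t, switch_times)
        if a0 <= 0.0:
            if boundary >= t_end:
                break
            t = boundary
            continue
        dt = np.random.exponential(1.0 / a0)
        if t + dt > boundary:
            t = boundary
            continue
        t = t + dt
        if t >= t_end:
            break
        r = np.random.random() * a0
        acc = 0.0
        j = 0
        for j in range(a.size):
            acc += a[j]
            if r < acc:
                break
        counts += stoich[j]
        if n >= max_events:
            return times, rids, -1, counts
        times[n] = t
        rids[n] = j
        n += 1
    return times, rids, n, counts


# Species indices of the bursting model (promoter + 8-step elongation chain
# with a parallel inclusion-committed chain).
# 0: Prom (0/1), 1..8: P1..P8, 9..16: I1..I8, 17: Incl, 18: Skip
@njit(cache=True)
def ssa_bursting(kon, koff, vsyn, kelong, ki, ks, d_i, d_s,
                 fb_s, fb_k, fb_n, bursting, feedback,
                 t_grid, seed):
    """Dedicated SSA for the bursting/feedback model (nonlinear propensity).

    The feedback channel converts P8 directly to Skip with per-molecule rate
    fb_s / (1 + (fb_k/Skip)**fb_n), zero when Skip == 0.  With
    ``bursting == 0`` the promoter stays on; with ``feedback == 0`` the
    feedback channel is off.  Returns counts sampled on ``t_grid``.
    """
    np.random.seed(seed)
    n_species = 19
    counts = np.zeros(n_species, dtype=np.int64)
    counts[0] = 1  # active promoter, no pre-existing transcripts
    out = np.zeros((t_grid.size, n_species), dtype=np.int64)
    # reactions enumerated inline; propensity vector:
    # 0 prom off->on, 1 prom on->off, 2 initiation,
    # 3..9 P1..P7 elongation, 10..17 P1..P8 inclusion commitment,
    # 18..24 I1..I7 elongation, 25 I8 maturation -> Incl,
    # 26 P8 -> Skip basal, 27 P8 -> Skip feedback,
    # 28 Incl degradation, 29 Skip degradation
    n_react = 30
    a = np.zeros(n_react)
    t = 0.0
    gi = 0
    t_end = t_grid[-1]
    while True:
        if bursting != 0:
            a[0] = kon * (1 - counts[0])
            a[1] = koff * counts[0]
        else:
            a[0] = 0.0
            a[1] = 0.0
        a[2] = vsyn * counts[0]
        for i in range(7):
            a[3 + i] = kelong * counts[1 + i]
        for i in range(8):
            a[10 + i] = ki * counts[1 + i]
        for i in range(7):
            a[18 + i] = kelong * counts[9 + i]
        a[25] = kelong * counts[16]
        a[26] = ks * counts[8]
        if feedback != 0 and counts[18] > 0:
            a[27] = counts[8] * fb_s / (1.0 + (fb_k / counts[18]) ** fb_n)
        else:
            a[27] = 0.0
        a[28] = d_i * counts[17]
        a[29] = d_s * counts[18]
        a0 = 0.0
        for j in range(n_react):
            a0 += a[j]
        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / a0)
        while gi < t_grid.size and t_grid[gi] < t_next:
            out[gi] = counts
            gi += 1
        if t_next > t_end or gi >= t_grid.size:
            break
        t = t_next
        r = np.random.random() * a0
        acc = 0.0
        j = 0
        for j in range(n_react):
            acc += a[j]
            if r < acc:
                break
        if j == 0:
            counts[0] = 1
        elif j == 1:
            counts[0] = 0
        elif j == 2:
            counts[1] += 1
        elif j < 10:
            i = j - 3
            counts[1 + i] -= 1
            counts[2 + i] += 1
        elif j < 18:
            i = j - 10
            counts[1 + i] -= 1
            counts[9 + i] += 1
        elif j < 25:
            i = j - 18
            counts[9 + i] -= 1
            counts[10 + i] += 1
        elif j == 25:
            counts[16] -= 1
            counts[17] += 1
        elif j == 26 or j == 27:
            counts[8] -= 1
            counts[18] += 1
        elif j == 28:
            counts[17] -= 1
        else:
            counts[18] -= 1
    while gi < t_grid.size:
        out[gi] = counts
        gi += 1
    return out
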