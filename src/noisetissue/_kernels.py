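"""Numba-compiled stochastic simulation kernels.

All kernels simulate the linear two-stage expression scheme

    0 -> mRNA            (rate v0)
    mRNA -> 0            (rate d0 * m)
    mRNA -> mRNA + P     (rate v1 * m)
    P -> 0               (rate d1 * p)

with the exact direct method (Gillespie). The photoconverted red pool is a
pure death process fed only by the conversion event, so red copy numbers are
sampled by sequential binomial thinning between output times, which is
distribution-exact and avoids simulating its jumps.

Seeds passed to kernels must fit in 32 bits (numba's np.random.seed).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sim_mg(v0, d0, v1, d1, m, g, t, t_end, seed):
    """Advance one (mRNA, protein) pair from t to t_end; return final counts."""
    np.random.seed(seed)
    while True:
        a1 = v0
        a2 = d0 * m
        a3 = v1 * m
        a4 = d1 * g
        atot = a1 + a2 + a3 + a4
        if atot <= 0.0:
            return m, g
        t += -np.log(np.random.random()) / atot
        if t > t_end:
            return m, g
        u = np.random.random() * atot
        if u < a1:
            m += 1
        elif u < a1 + a2:
            m -= 1
        elif u < a1 + a2 + a3:
            g += 1
        else:
            g -= 1


@njit(cache=True)
def sim_mg_grid(v0, d0, v1, d1, m0, g0, t_grid, seed):
    """Sample one (mRNA, protein) path at the times in t_grid (ascending,
    measured from the initial state). Returns (m, g) integer arrays."""
    np.random.seed(seed)
    n = t_grid.shape[0]
    m_out = np.empty(n, dtype=np.int64)
    g_out = np.empty(n, dtype=np.int64)
    m = m0
    g = g0
    t = 0.0
    k = 0
    t_next = np.inf  # time of the next reaction, drawn lazily
    while k < n:
        a1 = v0
        a2 = d0 * m
        a3 = v1 * m
        a4 = d1 * g
        atot = a1 + a2 + a3 + a4
        if atot <= 0.0:
            while k < n:
                m_out[k] = m
                g_out[k] = g
                k += 1
            return m_out, g_out
        t_next = t + (-np.log(np.random.random()) / atot)
        while k < n and t_grid[k] < t_next:
            m_out[k] = m
            g_out[k] = g
            k += 1
        if k >= n:
            return m_out, g_out
        t = t_next
        u = np.random.random() * atot
        if u < a1:
            m += 1
        elif u < a1 + a2:
            m -= 1
        elif u < a1 + a2 + a3:
            g += 1
        else:
            g -= 1
    return m_out, g_out


@njit(cache=True)
def thin_death(x0, d, dts, seed):
    """Exact pure-death sample path: counts after each successive interval
    in dts, by sequential binomial thinning with survival exp(-d*dt)."""
    np.random.seed(seed)
    n = dts.shape[0]
    out = np.empty(n, dtype=np.int64)
    x = x0
    for i in range(n):
        p = np.exp(-d * dts[i])
        x = np.random.binomial(x, p)
        out[i] = x
    return out


@njit(cache=True)
def ensemble_green_pair(v0, d0, d1, v1s, m0s, t1, t2, seeds):
    """Post-conversion green counts at t1 and t2 for an ensemble.

    Each trajectory i starts at conversion time 0 with green = 0 and
    mRNA = m0s[i] (a stationary draw), and uses translation rate v1s[i].
    """
    n = v1s.shape[0]
    g1 = np.empty(n, dtype=np.int64)
    g2 = np.empty(n, dtype=np.int64)
    for i in range(n):
        m, g = sim_mg(v0, d0, v1s[i], d1, m0s[i], 0, 0.0, t1, seeds[i])
        g1[i] = g
        m, g = sim_mg(v0, d0, v1s[i], d1, m, g, t1, t2, seeds[i] + 1)
        g2[i] = g
    return g1, g2


@njit(cache=True)
def ensemble_moments_grid(v0, d0, v1, d1, m0s, g0s, t_grid, seeds):
    """mRNA and protein counts at grid times for an ensemble of trajectories
    with common rates. Returns (n_traj, n_times) integer arrays."""
    n = m0s.shape[0]
    nt = t_grid.shape[0]
    m_out = np.empty((n, nt), dtype=np.int64)
    g_out = np.empty((n, nt), dtype=np.int64)
    for i in range(n):
        m_path, g_path = sim_mg_grid(v0, d0, v1, d1, m0s[i], g0s[i], t_grid, seeds[i])
        m_out[i] = m_path
        g_out[i] = g_path
    return m_out, g_out


@njit(cache=True)
def ensemble_conversion_timecourse(v0, d0, d1, v1s, m0s, g0s, t_grid, seeds):
    """Green and red counts at t_grid (times >= 0 measured from conversion)
    for an ensemble. At conversion the full green pool g0s[i] becomes red and
    then decays; green regrows from 0 driven by the surviving mRNA pool."""
    n = v1s.shape[0]
    nt = t_grid.shape[0]
    g_out = np.empty((n, nt), dtype=np.int64)
    r_out = np.empty((n, nt), dtype=np.int64)
    dts = np.empty(nt)
    prev = 0.0
    for j in range(nt):
        dts[j] = t_grid[j] - prev
        prev = t_grid[j]
    for i in range(n):
        m_path, g_path = sim_mg_grid(v0, d0, v1s[i], d1, m0s[i], 0, t_grid, seeds[i])
        g_out[i] = g_path
        r_out[i] = thin_death(g0s[i], d1, dts, seeds[i] + 1)
    return g_out, r_out


@njit(cache=True)
def ensemble_division_pairs(v0, d0, d1, v1_mother, v1_d1, v1_d2, g0_means,
                            ages, burn, seeds):
    """Mother/daughter inheritance ensemble for the dual-reporter system.

    For each pair i: the mother holds two reporters (C, Y) sharing the
    translation rate v1_mother[i]; its stationary state is reached by a
    burn-in of `burn` hours from (Poisson mRNA, deterministic mean protein).
    Both daughters copy the mother's exact mRNA and protein counts and then
    evolve independently for ages[i] hours with their own translation rates
    (v1_d1 / v1_d2, each applied to both of that daughter's reporters).

    Returns an (n, 4) array of final counts: C1, Y1, C2, Y2.
    """
    n = v1_mother.shape[0]
    out = np.empty((n, 4), dtype=np.int64)
    for i in range(n):
        s = seeds[i]
        np.random.seed(s)
        mc0 = np.random.poisson(v0 / d0)
        my0 = np.random.poisson(v0 / d0)
        g0 = int(g0_means[i])
        mc, gc = sim_mg(v0, d0, v1_mother[i], d1, mc0, g0, 0.0, burn, s + 1)
        my, gy = sim_mg(v0, d0, v1_mother[i], d1, my0, g0, 0.0, burn, s + 2)
        _, c1 = sim_mg(v0, d0, v1_d1[i], d1, mc, gc, 0.0, ages[i], s + 3)
        _, y1 = sim_mg(v0, d0, v1_d1[i], d1, my, gy, 0.0, ages[i], s + 4)
        _, c2 = sim_mg(v0, d0, v1_d2[i], d1, mc, gc, 0.0, ages[i], s + 5)
        _, y2 = sim_mg(v0, d0, v1_d2[i], d1, my, gy, 0.0, ages[i], s + 6)
        out[i, 0] = c1
        out[i, 1] = y1
        out[i, 2] = c2
        out[i, 3] = y2
    return out


@njit(cache=True)
def ensemble_stationary(v0, d0, d1, v1s, g0_means, burn, seeds):
    """Stationary (mRNA, protein) draws for an ensemble of cells, each with
    its own translation rate: Poisson mRNA plus a burn-in from the supplied
    deterministic protein starting values."""
    n = v1s.shape[0]
    m_out = np.empty(n, dtype=np.int64)
    g_out = np.empty(n, dtype=np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        m0 = np.random.poisson(v0 / d0)
        g0 = int(g0_means[i])
        m, g = sim_mg(v0, d0, v1s[i], d1, m0, g0, 0.0, burn, seeds[i] + 1)
        m_out[i] = m
        g_out[i] = g
    return m_out, g_out


@njit(cache=True)
def stationary_burnin(v0, d0, v1, d1, burn, seed):
    """Draw one (mRNA, protein) state approximately from the stationary law:
    Poisson mRNA, protein started at its stationary mean, relaxed for `burn`
    hours (use burn >> 1/d1)."""
    np.random.seed(seed)
    m0 = np.random.poisson(v0 / d0)
    g0 = int(v0 * v1 / (d0 * d1))
    return sim_mg(v0, d0, v1, d1, m0, g0, 0.0, burn, seed + 1)
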