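"""Jit-compiled inner loops for the Metropolis and Random Transition dynamics.

The kernels use numba's per-thread NumPy RNG seeded explicitly at entry, so a
run is fully reproducible given its seed (within this implementation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mmc_run", "rtm_run"]


@njit(cache=True)
def mmc_run(
    spins,  # (L, L) int8 array in {-1, +1}; mutated in place
    beta,
    J,
    burn_in_samples,
    n_samples,
    seed,
    gated,  # bool: apply the directed gate below
    src_r,
    src_c,
    tgt_r,  # int64[:] target row coordinates
    tgt_c,  # int64[:] target col coordinates
    allowed_state,  # +1 or -1
    omega,  # causal lag in sample units (>= 1 when gated)
):
    """Metropolis Monte Carlo with periodic boundaries.

    One sample is recorded per L*L flipping considerations, so each site is
    on average considered once between samples.  When ``gated`` is set, a
    target site may only be considered while the source site's *sampled*
    state ``omega`` samples back equals ``allowed_state``; while fewer than
    ``omega`` samples exist the targets are held frozen.  The gate value is
    held constant between samples.

    Returns (S_trace, lattice_trace): per-sample total spin, and the full
    int8 lattice at every retained sample.
    """
    np.random.seed(seed)
    L = spins.shape[0]
    N = L * L
    total = burn_in_samples + n_samples
    S_trace = np.empty(n_samples, np.int64)
    lattice_trace = np.empty((n_samples, L, L), np.int8)

    hist = np.zeros(max(omega, 1), np.int8)  # ring buffer of sampled source states
    for k in range(total):
        if gated:
            if k >= omega:
                gate_open = hist[k % omega] == allowed_state
            else:
                gate_open = False  # warm-up: targets frozen
        else:
            gate_open = True
        for _ in range(N):
            r = np.random.randint(0, L)
            c = np.random.randint(0, L)
            if gated and not gate_open:
                is_target = False
                for j in range(tgt_r.shape[0]):
                    if r == tgt_r[j] and c == tgt_c[j]:
                        is_target = True
                        break
                if is_target:
                    continue
            s = spins[r, c]
            nb = (
                spins[(r + 1) % L, c]
                + spins[(r - 1) % L, c]
                + spins[r, (c + 1) % L]
                + spins[r, (c - 1) % L]
            )
            dE = 2.0 * J * s * nb
            if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                spins[r, c] = -s
        if gated:
            hist[k % omega] = spins[src_r, src_c]
        if k >= burn_in_samples:
            i = k - burn_in_samples
            S_trace[i] = np.sum(spins)
            lattice_trace[i] = spins
    return S_trace, lattice_trace


@njit(cache=True)
def rtm_run(M, p1, p2, p3, cond_mask, omega, n, seed, gated):
    """Random Transition model: source X1 and gated targets X2, X3.

    Each process, when it swaps, moves to one of the other M-1 states
    uniformly.  X1 swaps with probability p1 unconditionally; X2 (X3) may
    attempt its swap (prob p2, p3) only if X1's state omega steps earlier is
    in the conditioned set, else it is forced to stay.  Steps with
    t+1-omega < 0 hold the targets frozen.  Initial states are independent
    uniform.  ``gated=False`` gives three independent swap chains (the null
    model).
    """
    np.random.seed(seed)
    x1 = np.empty(n, np.int64)
    x2 = np.empty(n, np.int64)
    x3 = np.empty(n, np.int64)
    x1[0] = np.random.randint(0, M)
    x2[0] = np.random.randint(0, M)
    x3[0] = np.random.randint(0, M)
    for t in range(n - 1):
        if np.random.random() < p1:
            x1[t + 1] = (x1[t] + 1 + np.random.randint(0, M - 1)) % M
        else:
            x1[t + 1] = x1[t]
        if gated:
            gi = t + 1 - omega
            gate_open = gi >= 0 and cond_mask[x1[gi]]
        else:
            gate_open = True
        if gate_open and np.random.random() < p2:
            x2[t + 1] = (x2[t] + 1 + np.random.randint(0, M - 1)) % M
        else:
            x2[t + 1] = x2[t]
        if gate_open and np.random.random() < p3:
            x3[t + 1] = (x3[t] + 1 + np.random.randint(0, M - 1)) % M
        else:
            x3[t + 1] = x3[t]
    return x1, x2, x3
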