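"""Numba inner loops for the exhaustive computability sweeps.

Interior configurations of width n are packed big-endian into integers
(cell 0 is the most significant bit). Each kernel runs every one of the
2^n initial interior states to the horizon T under a clamped constant
boundary pair, filling a first-hitting-time matrix ``fh`` (entry
``fh[init, state]`` is the smallest t >= 1 at which the trajectory from
``init`` occupies ``state``; -1 if never within the horizon) and the
array of final states at t = T.

The probabilistic kernel draws its per-cell coins from the Mersenne
Twister stream seeded inside the kernel, one uniform per interior cell
per step, cell 0 first, initial states processed in increasing order.
The pure-Python reference in the test suite mirrors that draw order
with ``numpy.random.RandomState``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sync_firsthit(table, T, fh, final):  # pragma: no cover - exercised via wrapper
    """Deterministic dynamics given a precomputed state-transition table."""
    size = table.shape[0]
    for init in range(size):
        state = init
        for t in range(1, T + 1):
            state = table[state]
            if fh[init, state] < 0:
                fh[init, state] = t
        final[init] = state


@njit(cache=True)
def async_firsthit(outputs, n, T, p, bl, br, seed, fh, final):  # pragma: no cover
    """Probabilistically asynchronous dynamics: keep each cell w.p. p."""
    np.random.seed(seed)
    size = 1 << n
    c = np.empty(n, np.uint8)
    new = np.empty(n, np.uint8)
    for init in range(size):
        for i in range(n):
            c[i] = (init >> (n - 1 - i)) & 1
        state = init
        for t in range(1, T + 1):
            for i in range(n):
                x = c[i - 1] if i > 0 else bl
                z = c[i + 1] if i < n - 1 else br
                s = 4 * x + 2 * c[i] + z
                if np.random.random() < p:
                    new[i] = c[i]
                else:
                    new[i] = outputs[s]
            state = 0
            for i in range(n):
                c[i] = new[i]
                state = (state << 1) | c[i]
            if fh[init, state] < 0:
                fh[init, state] = t
        final[init] = state


@njit(cache=True)
def at_firsthit(passive, n, T, bl, br, seed, literal_a0, fh, final):  # pragma: no cover
    """Asynchronously tuned dynamics; every trajectory draws fresh orders.

    Each step of each trajectory samples an update order by ranking n
    uniform keys (drawn from the seeded Mersenne Twister stream, initial
    states in increasing order). Update-case codes are 0 ACTIVE_MIN,
    1 LEFT_FIRST, 2 RIGHT_FIRST, 3 PASSIVE_MAX; under the clamped
    topology boundary neighbors always rank later. One evolving state
    array plus a time-t snapshot realizes the neighbor-substitution
    pattern of the four cases.
    """
    np.random.seed(seed)
    size = 1 << n
    c = np.empty(n, np.uint8)
    old = np.empty(n, np.uint8)
    e = np.empty((n, 8), np.uint8)
    rank = np.empty(n, np.int64)
    for init in range(size):
        for i in range(n):
            c[i] = (init >> (n - 1 - i)) & 1
            for k in range(8):
                e[i, k] = passive[k]
        state = init
        for t in range(T):
            keys = np.random.random(n)
            proc = np.argsort(keys)
            for j in range(n):
                rank[proc[j]] = j + 1
            for i in range(n):
                old[i] = c[i]
            for idx in range(n):
                i = proc[idx]
                lrank = rank[i - 1] if i > 0 else n + 1
                rrank = rank[i + 1] if i < n - 1 else n + 1
                own = rank[i]
                if lrank > own and rrank > own:
                    case = 0
                elif lrank < own and own < rrank:
                    case = 1
                elif lrank > own and own > rrank:
                    case = 2
                else:
                    case = 3
                l = c[i - 1] if i > 0 else bl
                r = c[i + 1] if i < n - 1 else br
                s = 4 * l + 2 * c[i] + r
                if case == 0:
                    newv = e[i, s]
                else:
                    newv = passive[s]
                lo = old[i - 1] if i > 0 else bl
                ro = old[i + 1] if i < n - 1 else br
                m = 4 * lo + 2 * old[i] + ro
                if case == 1 or case == 2:
                    e[i, m] = passive[0] if literal_a0 else passive[m]
                elif case == 3:
                    e[i, m] = newv
                c[i] = newv
            state = 0
            for i in range(n):
                state = (state << 1) | c[i]
            if fh[init, state] < 0:
                fh[init, state] = t + 1
        final[init] = state
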