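"""Numba core for degree-preserving Metropolis target swaps.

The chain keeps every node's in- and out-degree fixed and moves the
in-degree correlation of the edge ends by swapping the targets of random
edge pairs.  Membership tests ("would this swap create a duplicate edge?")
go through an open-addressing hash set over int64 edge keys src*N + tgt,
with tombstone deletion and periodic rebuild.  The Pearson coefficient is
tracked online: only the cross moment sum S_xy changes under a target swap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EMPTY = np.int64(-1)
_TOMB = np.int64(-2)


@njit(cache=True, inline="always")
def _mix(key: np.int64) -> np.int64:
    # splitmix64 finalizer; cheap avalanche for edge keys
    z = np.uint64(key) * np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return np.int64(z ^ (z >> np.uint64(31)))


@njit(cache=True, inline="always")
def _ht_contains(table, mask, key):
    i = _mix(key) & mask
    while True:
        v = table[i]
        if v == key:
            return True
        if v == _EMPTY:
            return False
        i = (i + 1) & mask


@njit(cache=True, inline="always")
def _ht_insert(table, mask, key):
    """Insert key (assumed absent); returns 1 if a tombstone was reused."""
    i = _mix(key) & mask
    first_tomb = np.int64(-1)
    while True:
        v = table[i]
        if v == _EMPTY:
            if first_tomb >= 0:
                table[first_tomb] = key
                return 1
            table[i] = key
            return 0
        if v == _TOMB and first_tomb < 0:
            first_tomb = i
        i = (i + 1) & mask


@njit(cache=True, inline="always")
def _ht_remove(table, mask, key):
    i = _mix(key) & mask
    while True:
        v = table[i]
        if v == key:
            table[i] = _TOMB
            return
        if v == _EMPTY:
            return
        i = (i + 1) & mask


@njit(cache=True)
def _ht_build(src, tgt, n_nodes, table):
    table[:] = _EMPTY
    mask = np.int64(table.shape[0] - 1)
    for e in range(src.shape[0]):
        _ht_insert(table, mask, np.int64(src[e]) * n_nodes + np.int64(tgt[e]))
    return mask


@njit(cache=True)
def metropolis_chain(
    src,
    tgt,
    kin,
    n_nodes,
    sign,
    g,
    n_attempts,
    seed,
    p_target,
    plateau_tol,
    plateau_window,
    check_interval,
):
    """Run the swap chain in place on tgt.

    sign=+1 accepts swaps that raise the edge-end in-degree covariance
    (assortative rule), sign=-1 the opposite.  ``p_target`` stops the chain
    once sign*p >= sign*p_target (pass +/-2.0 to disable).  ``plateau_tol``
    and ``plateau_window`` implement the plateau stop: the chain halts when
    p changed by less than plateau_tol over the last plateau_window
    checkpoints (one checkpoint per ``check_interval`` attempts, |E| when
    check_interval <= 0); pass plateau_window=0 to disable.  Returns
    (attempts_done, n_accepted, p_trace).
    """
    np.random.seed(seed)
    E = src.shape[0]
    nn = np.int64(n_nodes)

    cap = np.int64(8)
    while cap < 4 * E:
        cap *= 2
    table = np.empty(cap, dtype=np.int64)
    mask = _ht_build(src, tgt, nn, table)
    tombs = 0

    # constant marginal moments of (x, y) = (kin[src], kin[tgt])
    sx = 0.0
    sxx = 0.0
    sy = 0.0
    syy = 0.0
    sxy = 0.0
    for e in range(E):
        x = float(kin[src[e]])
        y = float(kin[tgt[e]])
        sx += x
        sxx += x * x
        sy += y
        syy += y * y
        sxy += x * y
    mx = sx / E
    my = sy / E
    denom = np.sqrt((sxx / E - mx * mx) * (syy / E - my * my))

    check = check_interval if check_interval > 0 else (E if E > 0 else 1)
    n_checks = n_attempts // check + 2
    trace = np.empty(n_checks, dtype=np.float64)
    trace[0] = (sxy / E - mx * my) / denom
    tix = 1

    accepted = 0
    attempts = 0
    while attempts < n_attempts:
        stop = attempts + check
        if stop > n_attempts:
            stop = n_attempts
        while attempts < stop:
            attempts += 1
            e1 = np.random.randint(0, E)
            e2 = np.random.randint(0, E)
            if e1 == e2:
                continue
            s1 = src[e1]
            t1 = tgt[e1]
            s2 = src[e2]
            t2 = tgt[e2]
            if t1 == t2 or s1 == s2:
                continue
            if s1 == t2 or s2 == t1:
                continue  # would create a self-loop
            k1 = float(kin[s1])
            k2 = float(kin[s2])
            m1 = float(kin[t1])
            m2 = float(kin[t2])
            if g < 1.0 and np.random.random() >= g:
                pass  # unconditional random swap: erases correlations
            else:
                gain = sign * ((k1 * m2 + k2 * m1) - (k1 * m1 + k2 * m2))
                if gain <= 0.0:
                    continue
            key_new1 = np.int64(s1) * nn + np.int64(t2)
            key_new2 = np.int64(s2) * nn + np.int64(t1)
            if _ht_contains(table, mask, key_new1) or _ht_contains(
                table, mask, key_new2
            ):
                continue  # would create a duplicate edge
            _ht_remove(table, mask, np.int64(s1) * nn + np.int64(t1))
            _ht_remove(table, mask, np.int64(s2) * nn + np.int64(t2))
            tombs += 2
            tombs -= _ht_insert(table, mask, key_new1)
            tombs -= _ht_insert(table, mask, key_new2)
            tgt[e1] = t2
            tgt[e2] = t1
            sxy += (k1 - k2) * (m2 - m1)
            accepted += 1
            if tombs > cap // 4:
                mask = _ht_build(src, tgt, nn, table)
                tombs = 0
        p_now = (sxy / E - mx * my) / denom
        trace[tix] = p_now
        tix += 1
        if sign * p_now >= sign * p_target:
            break
        if plateau_window > 0 and tix > plateau_window:
            if abs(p_now - trace[tix - 1 - plateau_window]) < plateau_tol:
                break
    return attempts, accepted, trace[:tix]
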