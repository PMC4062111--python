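"""Compiled exact-SSA kernels (next-reaction method and direct method).

Array encoding shared by both kernels:

* ``order``  -- 1 or 2 reactant molecules per reaction
* ``r1, r2`` -- reactant species indices (``r2 = -1`` for unimolecular)
* ``homo``   -- 1 when the reaction consumes two copies of the same species
* ``kvec``   -- stochastic rate constants
* ``delta``  -- (n_reactions, n_species) net count change per firing
* ``dep_ptr, dep_idx`` -- CSR adjacency: reactions whose propensity changes
  after reaction j fires (including j itself)

States are recorded on a fixed time grid (state just before each grid
time), not per event, to bound memory.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_MAX_EVENTS = 2_000_000_000


@njit(cache=True)
def _propensity(j, x, order, r1, r2, homo, kvec):
    if order[j] == 1:
        return kvec[j] * x[r1[j]]
    if homo[j] == 1:
        n = x[r1[j]]
        return kvec[j] * n * (n - 1.0) * 0.5
    return kvec[j] * x[r1[j]] * x[r2[j]]


@njit(cache=True)
def ssa_direct(order, r1, r2, homo, kvec, delta, dep_ptr, dep_idx, x0, t_end, grid, seed):
    np.random.seed(seed)
    n_r = order.shape[0]
    n_s = x0.shape[0]
    n_g = grid.shape[0]
    x = x0.astype(np.float64)
    out = np.zeros((n_g, n_s))
    a = np.zeros(n_r)
    for j in range(n_r):
        a[j] = _propensity(j, x, order, r1, r2, homo, kvec)
    a_sum = a.sum()
    t = 0.0
    g = 0
    events = 0
    while g < n_g and grid[g] <= t:
        for s in range(n_s):
            out[g, s] = x[s]
        g += 1
    while t < t_end and g < n_g:
        if a_sum <= 0.0:
            break
        tau = np.random.exponential(1.0 / a_sum)
        t_next = t + tau
        while g < n_g and grid[g] < t_next:
            for s in range(n_s):
                out[g, s] = x[s]
            g += 1
        if g >= n_g or t_next > t_end:
            t = t_next
            break
        # pick reaction
        u = np.random.random() * a_sum
        mu = 0
        acc = a[0]
        while acc < u and mu < n_r - 1:
            mu += 1
            acc += a[mu]
        for s in range(n_s):
            x[s] += delta[mu, s]
        t = t_next
        for p in range(dep_ptr[mu], dep_ptr[mu + 1]):
            j = dep_idx[p]
            a_sum -= a[j]
            a[j] = _propensity(j, x, order, r1, r2, homo, kvec)
            a_sum += a[j]
        if a_sum < 0.0:  # numerical drift guard
            a_sum = a.sum()
        events += 1
        if events >= _MAX_EVENTS:
            break
    while g < n_g:
        for s in range(n_s):
            out[g, s] = x[s]
        g += 1
    return out, events


@njit(cache=True)
def _heap_swap(heap_key, heap_node, pos, i, j):
    ki = heap_key[i]
    heap_key[i] = heap_key[j]
    heap_key[j] = ki
    ni = heap_node[i]
    heap_node[i] = heap_node[j]
    heap_node[j] = ni
    pos[heap_node[i]] = i
    pos[heap_node[j]] = j


@njit(cache=True)
def _heap_update(heap_key, heap_node, pos, node, new_key):
    i = pos[node]
    heap_key[i] = new_key
    n = heap_key.shape[0]
    # sift up
    while i > 0:
        parent = (i - 1) // 2
        if heap_key[i] < heap_key[parent]:
            _heap_swap(heap_key, heap_node, pos, i, parent)
            i = parent
        else:
            break
    # sift down
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < n and heap_key[left] < heap_key[smallest]:
            smallest = left
        if right < n and heap_key[right] < heap_key[smallest]:
            smallest = right
        if smallest == i:
            break
        _heap_swap(heap_key, heap_node, pos, i, smallest)
        i = smallest


@njit(cache=True)
def ssa_next_reaction(order, r1, r2, homo, kvec, delta, dep_ptr, dep_idx, x0, t_end, grid, seed):
    """Gibson-Bruck next-reaction method with an indexed binary min-heap."""
    np.random.seed(seed)
    n_r = order.shape[0]
    n_s = x0.shape[0]
    n_g = grid.shape[0]
    x = x0.astype(np.float64)
    out = np.zeros((n_g, n_s))
    INF = np.inf

    a = np.zeros(n_r)
    tau = np.zeros(n_r)
    for j in range(n_r):
        a[j] = _propensity(j, x, order, r1, r2, homo, kvec)
        if a[j] > 0.0:
            tau[j] = np.random.exponential(1.0 / a[j])
        else:
            tau[j] = INF

    heap_key = tau.copy()
    heap_node = np.arange(n_r, dtype=np.int64)
    pos = np.arange(n_r, dtype=np.int64)
    # heapify
    for start in range(n_r // 2 - 1, -1, -1):
        i = start
        while True:
            left = 2 * i + 1
            right = left + 1
            smallest = i
            if left < n_r and heap_key[left] < heap_key[smallest]:
                smallest = left
            if right < n_r and heap_key[right] < heap_key[smallest]:
                smallest = right
            if smallest == i:
                break
            _heap_swap(heap_key, heap_node, pos, i, smallest)
            i = smallest

    t = 0.0
    g = 0
    events = 0
    while g < n_g and grid[g] <= t:
        for s in range(n_s):
            out[g, s] = x[s]
        g += 1
    while g < n_g:
        mu = heap_node[0]
        t_next = heap_key[0]
        while g < n_g and grid[g] < t_next:
            for s in range(n_s):
                out[g, s] = x[s]
            g += 1
        if g >= n_g or t_next > t_end or t_next == INF:
            break
        t = t_next
        for s in range(n_s):
            x[s] += delta[mu, s]
        for p in range(dep_ptr[mu], dep_ptr[mu + 1]):
            j = dep_idx[p]
            a_old = a[j]
            a_new = _propensity(j, x, order, r1, r2, homo, kvec)
            a[j] = a_new
            if j == mu:
                if a_new > 0.0:
                    new_tau = t + np.random.exponential(1.0 / a_new)
                else:
                    new_tau = INF
            else:
                old_tau = tau[j]
                if a_new <= 0.0:
                    new_tau = INF
                elif old_tau == INF or a_old <= 0.0:
                    new_tau = t + np.random.exponential(1.0 / a_new)
                else:
                    new_tau = t + (a_old / a_new) * (old_tau - t)
            tau[j] = new_tau
            _heap_update(heap_key, heap_node, pos, j, new_tau)
        events += 1
        if events >= _MAX_EVENTS:
            break
    while g < n_g:
        for s in range(n_s):
            out[g, s] = x[s]
        g += 1
    return out, events
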