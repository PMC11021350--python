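"""Low-level numerical kernels for monotonic and conjoint monotonic regression.

Everything here operates on plain float64 arrays and integer permutations so
that the hot paths (tens of thousands of CMR fits inside bootstrap loops) can
be JIT-compiled with numba.  A pure-Python fallback keeps the package
importable if numba is unavailable; the algorithms are identical.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def pava(values, weights):
    """Weighted pool-adjacent-violators: least-squares nondecreasing fit.

    Returns the fitted vector.  Standard stack-of-blocks formulation:
    each new point starts a block; blocks whose mean exceeds the incoming
    block's mean are merged into a weighted mean until monotone.
    """
    n = values.shape[0]
    fitted = np.empty(n, dtype=np.float64)
    block_val = np.empty(n, dtype=np.float64)
    block_wt = np.empty(n, dtype=np.float64)
    block_len = np.empty(n, dtype=np.int64)
    nb = 0
    for i in range(n):
        cur_val = values[i]
        cur_wt = weights[i]
        cur_len = 1
        while nb > 0 and block_val[nb - 1] > cur_val:
            tot = block_wt[nb - 1] + cur_wt
            cur_val = (block_val[nb - 1] * block_wt[nb - 1] + cur_val * cur_wt) / tot
            cur_wt = tot
            cur_len += block_len[nb - 1]
            nb -= 1
        block_val[nb] = cur_val
        block_wt[nb] = cur_wt
        block_len[nb] = cur_len
        nb += 1
    k = 0
    for b in range(nb):
        for _ in range(block_len[b]):
            fitted[k] = block_val[b]
            k += 1
    return fitted


@njit(cache=True)
def pava_sse(values, weights):
    """Weighted SSE of the best nondecreasing fit to ``values``."""
    fitted = pava(values, weights)
    sse = 0.0
    for i in range(values.shape[0]):
        d = values[i] - fitted[i]
        sse += weights[i] * d * d
    return sse


@njit(cache=True)
def conjoint_sse(x, y, wx, wy, order):
    """Combined weighted SSE of the two isotonic fits under a common order."""
    n = order.shape[0]
    bx = np.empty(n, dtype=np.float64)
    bw = np.empty(n, dtype=np.float64)
    for i in range(n):
        bx[i] = x[order[i]]
        bw[i] = wx[order[i]]
    total = pava_sse(bx, bw)
    for i in range(n):
        bx[i] = y[order[i]]
        bw[i] = wy[order[i]]
    total += pava_sse(bx, bw)
    return total


@njit(cache=True)
def local_search(x, y, wx, wy, order):
    """Adjacent-transposition descent from ``order``; first improvement.

    Returns (locally optimal order, its conjoint SSE).  The input array is
    not modified.
    """
    cur = order.copy()
    n = cur.shape[0]
    best = conjoint_sse(x, y, wx, wy, cur)
    improved = True
    while improved and best > 1e-15:
        improved = False
        for i in range(n - 1):
            tmp = cur[i]
            cur[i] = cur[i + 1]
            cur[i + 1] = tmp
            s = conjoint_sse(x, y, wx, wy, cur)
            if s < best - 1e-12:
                best = s
                improved = True
            else:
                tmp = cur[i]
                cur[i] = cur[i + 1]
                cur[i + 1] = tmp
    return cur, best


@njit(cache=True)
def exhaustive_search(x, y, wx, wy):
    """Minimum conjoint SSE over all total orders (Heap's algorithm).

    Only sensible for small n (factorial cost); the public API guards at
    n <= 8.
    """
    n = x.shape[0]
    perm = np.arange(n)
    counters = np.zeros(n, dtype=np.int64)
    best = conjoint_sse(x, y, wx, wy, perm)
    best_perm = perm.copy()
    i = 0
    while i < n:
        if counters[i] < i:
            if i % 2 == 0:
                tmp = perm[0]
                perm[0] = perm[i]
                perm[i] = tmp
            else:
                tmp = perm[counters[i]]
                perm[counters[i]] = perm[i]
                perm[i] = tmp
            s = conjoint_sse(x, y, wx, wy, perm)
            if s < best:
                best = s
                best_perm = perm.copy()
            counters[i] += 1
            i = 0
        else:
            counters[i] = 0
            i += 1
    return best_perm, best


def branch_and_bound(x, y, wx, wy, incumbent_order, incumbent_sse, max_nodes=2_000_000):
    """Exact permutation search by depth-first branch and bound.

    The order is built left to right.  The lower bound for a partial prefix
    is the conjoint SSE of the prefix itself: any completion restricted to
    the prefix is a feasible prefix fit, and SSE only accumulates, so the
    prefix optimum can never overestimate the full optimum.

    Returns (order, sse, completed).  ``completed`` is False when the node
    budget was exhausted, in which case the incumbent is returned as-is.
    """
    n = x.shape[0]
    best = float(incumbent_sse)
    best_order = np.asarray(incumbent_order, dtype=np.int64).copy()
    prefix = np.empty(n, dtype=np.int64)
    nodes = 0
    completed = True

    def descend(depth, remaining):
        nonlocal best, best_order, nodes, completed
        if not completed:
            return
        if depth == n:
            sse = conjoint_sse(x, y, wx, wy, prefix)
            if sse < best - 1e-15:
                best = sse
                best_order = prefix.copy()
            return
        for idx in list(remaining):
            nodes += 1
            if nodes > max_nodes:
                completed = False
                return
            prefix[depth] = idx
            bound = conjoint_sse(x, y, wx, wy, prefix[: depth + 1])
            if bound < best - 1e-12:
                remaining.remove(idx)
                descend(depth + 1, remaining)
                remaining.add(idx)

    descend(0, set(range(n)))
    return best_order, best, completed


def warm_up():
    """Trigger JIT compilation of all kernels on a tiny problem."""
    x = np.array([0.2, 0.1, 0.3], dtype=np.float64)
    y = np.array([0.1, 0.3, 0.2], dtype=np.float64)
    w = np.ones(3, dtype=np.float64)
    order = np.arange(3, dtype=np.int64)
    pava(x, w)
    pava_sse(x, w)
    conjoint_sse(x, y, w, w, order)
    local_search(x, y, w, w, order)
    exhaustive_search(x, y, w, w)
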