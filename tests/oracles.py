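"""Independent brute-force oracles used to verify the fast implementation.

These deliberately avoid the package's own PAVA/search code paths:
the one-variable oracle solves the order-constrained least-squares problem
by enumerating ordered block partitions; the conjoint oracle enumerates
every total order and scores each with scikit-learn's isotonic regression.
"""

from itertools import permutations

import numpy as np
from sklearn.isotonic import isotonic_regression


def _partitions(n):
    """All ways to cut 0..n-1 into contiguous blocks (2**(n-1) of them)."""
    if n == 1:
        yield [(0, 1)]
        return
    for cut_mask in range(2 ** (n - 1)):
        blocks = []
        start = 0
        for i in range(n - 1):
            if cut_mask >> i & 1:
                blocks.append((start, i + 1))
                start = i + 1
        blocks.append((start, n))
        yield blocks


def isotonic_oracle(values, weights=None):
    """Exact order-constrained weighted least squares by enumerating block
    partitions; each block is fitted with its weighted mean and a partition
    is feasible when the block means are weakly nondecreasing."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    best_sse = np.inf
    best_fit = None
    for blocks in _partitions(n):
        fit = np.empty(n)
        for lo, hi in blocks:
            fit[lo:hi] = np.average(values[lo:hi], weights=weights[lo:hi])
        block_means = [fit[lo] for lo, _ in blocks]
        if any(b2 < b1 - 1e-12 for b1, b2 in zip(block_means, block_means[1:])):
            continue
        sse = float(np.sum(weights * (values - fit) ** 2))
        if sse < best_sse:
            best_sse = sse
            best_fit = fit
    return best_fit, best_sse


def _iso_sse(values, weights):
    fit = isotonic_regression(values, sample_weight=weights, increasing=True)
    return float(np.sum(weights * (values - fit) ** 2))


def exhaustive_cmr_oracle(x, y, wx=None, wy=None):
    """Minimum conjoint misfit over all total orders, scored by sklearn."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    wx = np.ones(n) if wx is None else np.asarray(wx, dtype=float)
    wy = np.ones(n) if wy is None else np.asarray(wy, dtype=float)
    best = np.inf
    for perm in permutations(range(n)):
        idx = list(perm)
        sse = _iso_sse(x[idx], wx[idx]) + _iso_sse(y[idx], wy[idx])
        if sse < best:
            best = sse
    return best
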