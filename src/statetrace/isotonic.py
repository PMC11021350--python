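"""Weighted isotonic (monotonic) regression along an arbitrary condition order."""

from __future__ import annotations

import numpy as np

from . import _engine


def isotonic_fit(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    order: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares weakly nondecreasing fit to ``values`` along ``order``.

    Parameters
    ----------
    values
        Observed values, one per condition.
    weights
        Strictly positive precision weights; defaults to unit weights.
    order
        Permutation of condition indices along which the fitted values must
        be weakly nondecreasing; defaults to the identity order.

    Returns
    -------
    fitted, sse
        ``fitted`` is aligned with ``values`` (original index positions) and
        is weakly nondecreasing when read in ``order``; ``sse`` is the
        minimised weighted sum of squared deviations.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    n = values.shape[0]
    if weights is None:
        weights = np.ones(n, dtype=np.float64)
    else:
        weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != values.shape:
        raise ValueError(
            f"length mismatch: {n} values but {weights.shape[0]} weights"
        )
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    if order is None:
        order = np.arange(n, dtype=np.int64)
    else:
        order = np.asarray(order, dtype=np.int64)
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of condition indices")

    fitted_seq = _engine.pava(values[order], weights[order])
    fitted = np.empty(n, dtype=np.float64)
    fitted[order] = fitted_seq
    sse = float(np.sum(weights * (values - fitted) ** 2))
    return fitted, sse
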