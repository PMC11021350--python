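"""Conjoint monotonic regression (CMR) and the bootstrap test of the
single-latent-dimension null hypothesis.

State-trace logic: if two dependent variables are monotone functions of one
latent variable, their condition means must admit a COMMON total order of
conditions along which both are weakly nondecreasing.  CMR finds the order
minimising the combined weighted SSE of the two isotonic fits; the misfit
statistic is zero exactly when such an order exists.  A bootstrap that
regenerates data under the fitted monotonic null converts the misfit into a
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .isotonic import isotonic_fit

EXHAUSTIVE_MAX = 8
BRANCH_AND_BOUND_MAX = 14
_MONO_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StateTraceData:
    """Condition means of two dependent variables, ready for CMR.

    ``x_backing``/``y_backing`` are optional participant x condition value
    matrices (NaN where a participant does not contribute) used by the
    participant-resampling bootstrap.  ``strata`` assigns each backing row to
    a resampling stratum (e.g. the between-subjects emotion-perception
    group); participants are resampled within their stratum.
    """

    condition_labels: list
    x_means: np.ndarray
    y_means: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    dv_names: tuple[str, str] = ("x", "y")
    x_backing: np.ndarray | None = None
    y_backing: np.ndarray | None = None
    strata: np.ndarray | None = None

    def __post_init__(self):
        self.x_means = np.asarray(self.x_means, dtype=np.float64)
        self.y_means = np.asarray(self.y_means, dtype=np.float64)
        self.x_weights = np.asarray(self.x_weights, dtype=np.float64)
        self.y_weights = np.asarray(self.y_weights, dtype=np.float64)
        n = self.n_cond
        if n < 2:
            raise ValueError("at least 2 conditions are required")
        for name in ("y_means", "x_weights", "y_weights"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if len(self.condition_labels) != n:
            raise ValueError("condition_labels must match the number of conditions")
        if np.any(self.x_weights <= 0) or np.any(self.y_weights <= 0):
            raise ValueError("weights must be strictly positive")
        for mat, means in ((self.x_backing, self.x_means), (self.y_backing, self.y_means)):
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=np.float64)
            if mat.ndim != 2 or mat.shape[1] != n:
                raise ValueError("backing matrices must be participants x conditions")
            col = np.nanmean(mat, axis=0)
            if not np.allclose(col, means, atol=1e-8, equal_nan=True):
                raise ValueError("backing matrix means do not reproduce condition means")
        if self.strata is not None and self.x_backing is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.shape[0] != self.x_backing.shape[0]:
                raise ValueError("strata must label every backing row")

    @property
    def n_cond(self) -> int:
        return self.x_means.shape[0]

    def swapped(self) -> "StateTraceData":
        """The same dataset with the roles of the two variables exchanged."""
        return StateTraceData(
            condition_labels=list(self.condition_labels),
            x_means=self.y_means.copy(),
            y_means=self.x_means.copy(),
            x_weights=self.y_weights.copy(),
            y_weights=self.x_weights.copy(),
            dv_names=(self.dv_names[1], self.dv_names[0]),
            x_backing=None if self.y_backing is None else self.y_backing.copy(),
            y_backing=None if self.x_backing is None else self.x_backing.copy(),
            strata=None if self.strata is None else self.strata.copy(),
        )


@dataclass
class MonotonicModel:
    """Best-fitting conjoint monotonic model: a common total order of
    conditions plus the two weakly nondecreasing fitted vectors."""

    order: np.ndarray
    x_fitted: np.ndarray
    y_fitted: np.ndarray
    fit_stat: float
    exact: bool

    def is_monotone(self, tol: float = _MONO_TOL) -> bool:
        xo = self.x_fitted[self.order]
        yo = self.y_fitted[self.order]
        return bool(np.all(np.diff(xo) >= -tol) and np.all(np.diff(yo) >= -tol))


@dataclass
class CMRTestResult:
    """Observed CMR statistic, its bootstrap null distribution and p-values."""

    observed_stat: float
    boot_stats: np.ndarray
    p_value: float
    p_adjusted: float
    n_boot: int
    seed: int
    mode: str
    model: MonotonicModel
    dv_names: tuple[str, str] = ("x", "y")


@dataclass
class SummaryStatInput:
    """Per-condition (mean, sd, n) for both dependent variables.

    ``means``/``sds`` are (n_cond, 2) arrays with columns in ``dv_names``
    order; ``ns`` is (n_cond, 2) of positive integers.
    """

    condition_labels: list
    dv_names: tuple[str, str]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.ns = np.asarray(self.ns)
        k = len(self.condition_labels)
        for name in ("means", "sds", "ns"):
            if getattr(self, name).shape != (k, 2):
                raise ValueError(f"{name} must be shaped (n_cond, 2)")
        if np.any(self.sds <= 0):
            raise ValueError("sd must be strictly positive")
        if np.any(self.ns < 2):
            raise ValueError("n must be at least 2")

    @classmethod
    def from_csv(cls, path_or_buffer) -> "SummaryStatInput":
        """Read the delimited dialect ``condition,dv,mean,sd,n``."""
        df = pd.read_csv(path_or_buffer, sep=None, engine="python")
        expected = {"condition", "dv", "mean", "sd", "n"}
        if set(df.columns) != expected:
            raise ValueError(f"summary file must have columns {sorted(expected)}")
        dvs = list(pd.unique(df["dv"]))
        if len(dvs) != 2:
            raise ValueError("exactly two dependent variables are required")
        conds = list(pd.unique(df["condition"]))
        wide = df.set_index(["condition", "dv"])
        means = np.empty((len(conds), 2))
        sds = np.empty((len(conds), 2))
        ns = np.empty((len(conds), 2), dtype=np.int64)
        for i, c in enumerate(conds):
            for j, dv in enumerate(dvs):
                try:
                    row = wide.loc[(c, dv)]
                except KeyError:
                    raise ValueError(f"missing ({c}, {dv}) in summary input") from None
                means[i, j] = row["mean"]
                sds[i, j] = row["sd"]
                ns[i, j] = row["n"]
        return cls(conds, (str(dvs[0]), str(dvs[1])), means, sds, ns)

    def to_state_trace(self) -> StateTraceData:
        """Precision weights n / sd**2, per the normality assumption."""
        w = self.ns / self.sds**2
        return StateTraceData(
            condition_labels=list(self.condition_labels),
            x_means=self.means[:, 0],
            y_means=self.means[:, 1],
            x_weights=w[:, 0],
            y_weights=w[:, 1],
            dv_names=self.dv_names,
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_f64(a):
    return np.ascontiguousarray(a, dtype=np.float64)


def _heuristic_starts(x, y, wx, wy, extra=()):
    """Deterministic multistart orders: sort by each variable, by their
    precision-standardised sum, plus any caller-supplied warm starts."""
    n = x.shape[0]
    zx = (x - x.mean()) / (x.std() + 1e-12)
    zy = (y - y.mean()) / (y.std() + 1e-12)
    starts = [
        np.argsort(x, kind="stable"),
        np.argsort(y, kind="stable"),
        np.argsort(zx + zy, kind="stable"),
        np.arange(n),
    ]
    for e in extra:
        starts.append(np.asarray(e, dtype=np.int64))
    return [np.ascontiguousarray(s, dtype=np.int64) for s in starts]


def _multistart(x, y, wx, wy, extra_starts=()):
    best_order = None
    best = np.inf
    for start in _heuristic_starts(x, y, wx, wy, extra_starts):
        order, sse = _engine.local_search(x, y, wx, wy, start)
        if sse < best:
            best = sse
            best_order = order
        if best <= 1e-15:
            break
    return best_order, best


def _min_conjoint(x, y, wx, wy, method, warm=()):
    """Dispatch to the requested search strategy.

    Returns (order, sse, exact).
    """
    n = x.shape[0]
    x, y, wx, wy = map(_as_f64, (x, y, wx, wy))
    if method == "auto":
        if n <= EXHAUSTIVE_MAX:
            method = "exhaustive"
        elif n <= BRANCH_AND_BOUND_MAX:
            method = "branch_and_bound"
        else:
            method = "multistart_heuristic"
    if method == "exhaustive":
        if n > EXHAUSTIVE_MAX:
            raise ValueError(
                f"exhaustive search enumerates n! orders and is limited to "
                f"n_cond <= {EXHAUSTIVE_MAX} (got {n}); use "
                f"'branch_and_bound' or 'multistart_heuristic'"
            )
        order, sse = _engine.exhaustive_search(x, y, wx, wy)
        return order, sse, True
    if method == "branch_and_bound":
        inc_order, inc = _multistart(x, y, wx, wy, warm)
        if inc <= 1e-15:
            return inc_order, inc, True
        order, sse, completed = _engine.branch_and_bound(x, y, wx, wy, inc_order, inc)
        return order, sse, completed
    if method == "multistart_heuristic":
        order, sse = _multistart(x, y, wx, wy, warm)
        return order, sse, False
    raise ValueError(f"unknown method {method!r}")


def cmr_fit(data: StateTraceData, method: str = "auto") -> MonotonicModel:
    """Fit the conjoint monotonic regression model.

    ``method`` is one of ``auto`` (exhaustive up to 8 conditions, branch and
    bound to 14, multistart adjacent-transposition descent above),
    ``exhaustive``, ``branch_and_bound`` or ``multistart_heuristic``.  The
    returned model's ``exact`` flag records whether optimality is proven.
    """
    order, _, exact = _min_conjoint(
        data.x_means, data.y_means, data.x_weights, data.y_weights, method
    )
    x_fitted, sse_x = isotonic_fit(data.x_means, data.x_weights, order)
    y_fitted, sse_y = isotonic_fit(data.y_means, data.y_weights, order)
    return MonotonicModel(
        order=np.asarray(order, dtype=np.int64),
        x_fitted=x_fitted,
        y_fitted=y_fitted,
        fit_stat=float(sse_x + sse_y),
        exact=bool(exact),
    )


# ---------------------------------------------------------------------------
# bootstrap test
# ---------------------------------------------------------------------------


def _boot_method(n_cond: int, method: str) -> str:
    # Per-replicate strategy: exhaustive stays exact and fast for small
    # grids; branch and bound is too slow to run thousands of times, so the
    # bootstrap falls back to the multistart heuristic (the observed
    # statistic uses the same solver so the comparison is like-for-like).
    if method == "auto":
        return "exhaustive" if n_cond <= 7 else "multistart_heuristic"
    if method == "branch_and_bound":
        return "multistart_heuristic"
    return method


def _resampled_means(backing, strata, draws_by_stratum):
    """Column means after resampling rows within each stratum.

    ``draws_by_stratum`` maps stratum -> (B, n_s) row-index draws into that
    stratum's submatrix.  Conditions a stratum never observes stay NaN and
    are filled from the other strata.
    """
    B = next(iter(draws_by_stratum.values())).shape[0]
    n_cond = backing.shape[1]
    out = np.full((B, n_cond), np.nan)
    for s, draws in draws_by_stratum.items():
        rows = backing[strata == s] if strata is not None else backing
        chunk = 512
        m_s = np.empty((B, n_cond))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            for lo in range(0, B, chunk):
                sub = rows[draws[lo : lo + chunk]]  # (b, n_s, n_cond)
                m_s[lo : lo + chunk] = np.nanmean(sub, axis=1)
        take = ~np.isnan(m_s)
        out[take] = m_s[take]
    return out


def cmr_test(
    data: StateTraceData,
    n_boot: int = 10_000,
    seed: int = 0,
    mode: str = "participant_resample",
    method: str = "auto",
    m: int = 1,
) -> CMRTestResult:
    """Bootstrap test of the single-latent-dimension null.

    The null model is the best-fitting conjoint monotonic regression.  Each
    bootstrap replicate regenerates condition means under that null and
    refits CMR; the p-value is the add-one proportion of replicate
    statistics at least as large as the observed one.

    Modes
    -----
    participant_resample
        Resample participants with replacement within their stratum,
        recompute condition means, and recentre each resampled mean vector
        on the fitted monotonic values (mean shift, so the null holds
        exactly in the resampling population).  Requires backing matrices.
    parametric_normal
        Draw condition means from Normal(fitted, SE) with SE derived from
        the precision weights (SE = 1/sqrt(w)); this is the summary-
        statistics procedure.

    ``m`` is the Bonferroni multiplicity applied to ``p_adjusted``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if mode not in ("participant_resample", "parametric_normal"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")

    n = data.n_cond
    solver = _boot_method(n, method)
    x, y = _as_f64(data.x_means), _as_f64(data.y_means)
    wx, wy = _as_f64(data.x_weights), _as_f64(data.y_weights)

    obs_order, observed, _ = _min_conjoint(x, y, wx, wy, solver)
    x_fitted, sse_x = isotonic_fit(x, wx, obs_order)
    y_fitted, sse_y = isotonic_fit(y, wy, obs_order)
    observed = float(sse_x + sse_y)
    model = MonotonicModel(
        order=np.asarray(obs_order, dtype=np.int64),
        x_fitted=x_fitted,
        y_fitted=y_fitted,
        fit_stat=observed,
        exact=solver == "exhaustive",
    )

    rng = np.random.default_rng(seed)
    if mode == "participant_resample":
        if data.x_backing is None or data.y_backing is None:
            raise ValueError("participant_resample requires backing matrices")
        strata = data.strata
        labels = [None] if strata is None else list(pd.unique(strata))
        draws = {}
        for s in labels:
            n_s = (
                data.x_backing.shape[0]
                if strata is None
                else int(np.sum(strata == s))
            )
            draws[s] = rng.integers(0, n_s, size=(n_boot, n_s))
        bx = _resampled_means(data.x_backing, strata, draws)
        by = _resampled_means(data.y_backing, strata, draws)
        # recentre on the fitted null; empty resampled cells sit exactly on it
        bx = np.where(np.isnan(bx), x_fitted, bx - x + x_fitted)
        by = np.where(np.isnan(by), y_fitted, by - y + y_fitted)
    else:
        x_se = 1.0 / np.sqrt(wx)
        y_se = 1.0 / np.sqrt(wy)
        bx = rng.normal(x_fitted, x_se, size=(n_boot, n))
        by = rng.normal(y_fitted, y_se, size=(n_boot, n))

    boot_stats = np.empty(n_boot)
    warm = (np.asarray(obs_order, dtype=np.int64),)
    for b in range(n_boot):
        _, sse, _ = _min_conjoint(bx[b], by[b], wx, wy, solver, warm=warm)
        boot_stats[b] = sse

    count = int(np.sum(boot_stats >= observed - 1e-12))
    p_value = (1 + count) / (n_boot + 1)
    return CMRTestResult(
        observed_stat=observed,
        boot_stats=boot_stats,
        p_value=float(p_value),
        p_adjusted=float(adjust_pvalues([p_value], m)[0]),
        n_boot=int(n_boot),
        seed=int(seed),
        mode=mode,
        model=model,
        dv_names=data.dv_names,
    )


def cmr_from_summary(
    summary: SummaryStatInput,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    m: int = 1,
) -> CMRTestResult:
    """CMR bootstrap test from published (mean, sd, n) summaries.

    Precision weights are n/sd**2; the parametric bootstrap draws condition
    means from normal distributions centred on the monotonic fitted values
    with standard error sd/sqrt(n).
    """
    data = summary.to_state_trace()
    return cmr_test(
        data, n_boot=n_boot, seed=seed, mode="parametric_normal", method=method, m=m
    )


def adjust_pvalues(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    p = np.asarray(p_values, dtype=np.float64)
    if m < 1:
        raise ValueError("m must be at least 1")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, m * p)
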