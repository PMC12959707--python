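"""Aalen's additive hazards model on the event-time grid.

The conditional hazard is modelled as lambda(t | x) = beta_0(t) + sum_k
beta_k(t) x_k; what is estimable nonparametrically is the cumulative
coefficient B_k(t) = int_0^t beta_k(s) ds.  At each uncensored event time
t_j the least-squares increment is

    dB(t_j) = (X_j' X_j)^{-1} X_j' dN(t_j)

where X_j stacks the covariate rows (with intercept) of everyone at risk at
t_j — time-updated exposure states respected — and dN flags the failing
subject(s).  Tied failures are processed as a single grid point.  The
covariance increment is (X_j'X_j)^{-1} X_j' diag(dN) X_j (X_j'X_j)^{-1}.
Estimation stops at the first event time where X_j'X_j is numerically
singular (condition number above 1e12), which happens when late risk sets
no longer span the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, CountingProcessData

COND_LIMIT = 1e12


@dataclass
class CumulativeCoefficients:
    """Cumulative regression functions B(t) of the additive model.

    ``grid`` holds the uncensored event times used, ``B`` the cumulative
    coefficients (grid x covariates, intercept first), ``V`` the pointwise
    covariance estimates (grid x covariates x covariates).  B starts at 0
    and is piecewise constant between grid points; values are defined only
    up to ``estimable_until``.
    """

    grid: np.ndarray
    B: np.ndarray
    V: np.ndarray
    covariates: list[str]
    estimable_until: float

    @property
    def n_times(self) -> int:
        return len(self.grid)

    def column(self, covariate: str) -> np.ndarray:
        return self.B[:, self.covariates.index(covariate)]

    def variance(self, covariate: str) -> np.ndarray:
        k = self.covariates.index(covariate)
        return self.V[:, k, k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.covariates):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.grid,
                        "covariate": name,
                        "B": self.B[:, k],
                        "var": self.V[:, k, k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _extract(data, covariates):
    if isinstance(data, CountingProcessData):
        d = data.data
        start = d["start"].to_numpy(float)
        stop = d["stop"].to_numpy(float)
        status = d["status"].to_numpy(int)
    elif isinstance(data, CohortTable):
        d = data.data
        start = np.zeros(len(d))
        stop = d["time"].to_numpy(float)
        status = d["cause"].to_numpy(int)
    else:
        raise TypeError(f"unsupported data type {type(data)!r}")
    X = np.column_stack([np.ones(len(d)), d[list(covariates)].to_numpy(float)])
    return start, stop, status, X


def _aalen_ls(start, stop, status, X, cause=None, want_var=True):
    """Numpy core of the least-squares Aalen estimator.

    Returns (grid, B, V or None); raises ValueError when no events exist or
    the design is singular at the first event time.
    """
    p = X.shape[1]
    is_event = (status != 0) if cause is None else (status == cause)
    if not np.any(is_event):
        raise ValueError("no events of the requested cause")
    ev_times = np.unique(stop[is_event])

    if np.all(start == 0):
        return _aalen_ls_subject_level(stop, is_event, X, ev_times, want_var)

    grid = []
    incB = []
    incV = []
    for t in ev_times:
        at_risk = (start < t) & (t <= stop)
        Xj = X[at_risk]
        XtX = Xj.T @ Xj
        if Xj.shape[0] < p or np.linalg.cond(XtX) > COND_LIMIT:
            break
        Xf = Xj[is_event[at_risk] & (stop[at_risk] == t)]
        A = np.linalg.solve(XtX, Xf.T)  # p x d_j
        incB.append(A.sum(axis=1))
        if want_var:
            incV.append(A @ A.T)
        grid.append(t)
    if not grid:
        raise ValueError("design singular at the first event time")
    B = np.cumsum(np.asarray(incB), axis=0)
    V = np.cumsum(np.asarray(incV), axis=0) if want_var else None
    return np.asarray(grid), B, V


def _aalen_ls_subject_level(stop, is_event, X, ev_times, want_var):
    """Vectorized estimator for subject-level (start = 0) data.

    The risk set at t is {stop >= t}, a suffix of the stop-sorted rows, so
    every X_j'X_j comes from one cumulative sum of outer products and the
    per-event least-squares solves are batched.
    """
    n, p = X.shape
    order = np.argsort(stop, kind="stable")[::-1]
    Xs = X[order]
    cum_xtx = np.cumsum(Xs[:, :, None] * Xs[:, None, :], axis=0)
    n_at = n - np.searchsorted(np.sort(stop), ev_times, side="left")
    XtX = cum_xtx[n_at - 1]  # (E, p, p)

    # truncate at the first numerically singular design
    eig = np.linalg.eigvalsh(XtX)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(eig[:, 0] > 0, eig[:, -1] / eig[:, 0], np.inf)
    bad = (n_at < p) | (cond > COND_LIMIT)
    n_ok = int(np.argmax(bad)) if bad.any() else ev_times.size
    if n_ok == 0:
        raise ValueError("design singular at the first event time")
    ev_times = ev_times[:n_ok]
    XtX = XtX[:n_ok]

    # per-event sums of failing subjects' covariate rows
    ev_idx = np.searchsorted(ev_times, stop[is_event])
    keep = ev_idx < n_ok
    # stop times of events are exactly the ev_times; map each failure
    fail_sum = np.zeros((n_ok, p))
    np.add.at(fail_sum, ev_idx[keep], X[is_event][keep])
    incB = np.linalg.solve(XtX, fail_sum[:, :, None])[:, :, 0]
    B = np.cumsum(incB, axis=0)
    V = None
    if want_var:
        # sum over failing subjects of (XtX^-1 x_i)(XtX^-1 x_i)'
        A = np.linalg.solve(
            XtX[ev_idx[keep]], X[is_event][keep][:, :, None]
        )[:, :, 0]
        incV = np.zeros((n_ok, p, p))
        np.add.at(incV, ev_idx[keep], A[:, :, None] * A[:, None, :])
        V = np.cumsum(incV, axis=0)
    return ev_times, B, V


def fit_aalen(
    data, covariates: list[str], cause: int | None = None
) -> CumulativeCoefficients:
    """Least-squares Aalen estimator of the cumulative coefficients.

    ``cause`` restricts the counting process dN to one cause for
    cause-specific time-varying effects; the default counts deaths from
    either cause.  An intercept is always included (first column).
    """
    start, stop, status, X = _extract(data, covariates)
    grid, B, V = _aalen_ls(start, stop, status, X, cause=cause)
    return CumulativeCoefficients(
        grid=grid,
        B=B,
        V=V,
        covariates=["intercept", *covariates],
        estimable_until=float(grid[-1]),
    )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def constant_effect_slope(
    data,
    covariates: list[str],
    covariate: str,
    cause: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    cc: CumulativeCoefficients | None = None,
) -> tuple[float, float]:
    """Average-slope summary of one covariate's cumulative coefficient.

    slope = OLS slope of B_k(t_j) on t_j over the estimable grid — the
    "constant effect per year" a linear B would imply.  p is a two-sided
    bootstrap p-value from subject-level resamples testing slope = 0.

    Returns (slope per year, p).
    """
    if cc is None:
        cc = fit_aalen(data, covariates, cause=cause)
    if cc.n_times < 3:
        raise ValueError("fewer than 3 grid points; slope not estimable")
    slope = _ols_slope(cc.grid, cc.column(covariate))
    if n_boot <= 0:
        return slope, np.nan

    rng = np.random.default_rng(seed)
    start, stop, status, X = _extract(data, covariates)
    k_col = (["intercept", *covariates]).index(covariate)
    # subject-level (cluster) resampling: rows of one subject move together
    if isinstance(data, CountingProcessData):
        sid = data.data["subject_id"].to_numpy()
        _, first = np.unique(sid, return_index=True)
        codes = np.searchsorted(np.sort(first), np.arange(len(sid)), side="right") - 1
        # rows are contiguous per subject; group row indices per subject
        row_groups = [np.flatnonzero(codes == g) for g in range(len(first))]
        n = len(row_groups)
    else:
        row_groups = None
        n = len(start)
    boot_slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if row_groups is None:
            rows = idx
        else:
            rows = np.concatenate([row_groups[i] for i in idx])
        try:
            grid, B, _ = _aalen_ls(
                start[rows], stop[rows], status[rows], X[rows], cause=cause,
                want_var=False,
            )
            if grid.size < 3:
                continue
            boot_slopes.append(_ols_slope(grid, B[:, k_col]))
        except ValueError:
            continue
    boot_slopes = np.asarray(boot_slopes)
    if boot_slopes.size < max(10, n_boot // 4):
        raise ValueError("too many bootstrap resamples were degenerate")
    b = boot_slopes.size
    p_low = (1 + np.sum(boot_slopes <= 0)) / (b + 1)
    p_high = (1 + np.sum(boot_slopes >= 0)) / (b + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return slope, float(p)
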