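"""Cause-specific Cox and Fine-Gray subdistribution regression, plus Gray's test.

Both fitters maximize a (weighted) Breslow partial likelihood by
Newton-Raphson with step-halving.  The cause-specific Cox model censors
competing-cause failures at their failure time; the Fine-Gray model keeps
them in the risk set for the cause of interest with inverse-probability-of-
censoring weights w_i(t) = G(t)/G(min(T_i, t)), G the Kaplan-Meier estimate
of the censoring distribution.  Gray's test is computed as the score test
of the Fine-Gray model with group-indicator covariates at the null.

The risk-set sums are accumulated with suffix/prefix cumulative sums over
time-sorted rows, so one Newton iteration costs O(n log n + E p^2) rather
than O(E n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, CountingProcessData
from .nonparametric import censoring_survival

MAX_ITER = 50
SCORE_TOL = 1e-8
LL_RELTOL = 1e-10
COEF_CAP = 15.0


class FitError(RuntimeError):
    pass


@dataclass
class RegressionFit:
    """Result of a proportional-hazards fit on the log-hazard scale."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    kind: str  # "cox_cause_specific" | "fine_gray"
    cause: int
    converged: bool = True
    n_iter: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(0.975)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "se": self.se,
                "hr": self.hazard_ratios,
                "ci_low": lo,
                "ci_high": hi,
                "p": self.p_values,
            }
        )


@dataclass
class GrayTestResult:
    statistic: float
    df: int
    p: float


class _RiskSums:
    """Weighted Breslow risk-set sums over the event-time grid.

    Rows enter the risk set at ``start`` and leave after ``stop`` with unit
    weight; rows listed in ``late_idx`` re-enter after their stop time with
    time-varying weight G(t)/G(stop_i) (the Fine-Gray extension; empty for
    an ordinary Cox fit).
    """

    def __init__(self, start, stop, X, event_times, late_idx=None, G=None):
        self.X = X
        self.event_times = event_times
        n, p = X.shape
        self.p = p
        self.order_stop = np.argsort(stop, kind="stable")
        self.order_start = np.argsort(start, kind="stable")
        self.stop_sorted = stop[self.order_stop]
        self.start_sorted = start[self.order_start]
        # natural risk set at t: start < t <= stop
        self.pos_stop = np.searchsorted(self.stop_sorted, event_times, side="left")
        self.pos_start = np.searchsorted(self.start_sorted, event_times, side="left")
        self.late_idx = np.array([], dtype=int) if late_idx is None else late_idx
        if self.late_idx.size:
            self.G_at_stop = np.asarray(G(stop[self.late_idx]), dtype=float)
            self.G_at_events = np.asarray(G(event_times), dtype=float)
            order = np.argsort(stop[self.late_idx], kind="stable")
            self.late_sorted = self.late_idx[order]
            self.late_stop_sorted = stop[self.late_idx][order]
            self.late_G = self.G_at_stop[order]
            # late rows are at risk for t > stop_i (strictly after failure)
            self.pos_late = np.searchsorted(self.late_stop_sorted, event_times, side="left")

    def _suffix(self, arr):
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def sums(self, beta):
        """S0 (E,), S1 (E,p), S2 (E,p,p) of w * exp(x beta) * {1, x, xx'}."""
        X = self.X
        r = np.exp(X @ beta)
        rX = r[:, None] * X
        rXX = rX[:, :, None] * X[:, None, :]

        def risk_term(vals):
            sfx_stop = self._suffix(vals[self.order_stop])
            sfx_start = self._suffix(vals[self.order_start])
            pad = np.zeros((1, *vals.shape[1:]))
            sfx_stop = np.concatenate([sfx_stop, pad])
            sfx_start = np.concatenate([sfx_start, pad])
            return sfx_stop[self.pos_stop] - sfx_start[self.pos_start]

        S0 = risk_term(r[:, None])[:, 0]
        S1 = risk_term(rX)
        S2 = risk_term(rXX.reshape(len(r), -1)).reshape(-1, self.p, self.p)

        if self.late_idx.size:
            with np.errstate(divide="ignore", invalid="ignore"):
                inv_g = np.where(self.late_G > 0, 1.0 / self.late_G, 0.0)
            lr = r[self.late_sorted] * inv_g
            pre = np.concatenate([[0.0], np.cumsum(lr)])
            S0 = S0 + self.G_at_events * pre[self.pos_late]
            lrX = lr[:, None] * X[self.late_sorted]
            preX = np.concatenate([np.zeros((1, self.p)), np.cumsum(lrX, axis=0)])
            S1 = S1 + self.G_at_events[:, None] * preX[self.pos_late]
            lrXX = lrX[:, :, None] * X[self.late_sorted][:, None, :]
            preXX = np.concatenate(
                [np.zeros((1, self.p * self.p)), np.cumsum(lrXX.reshape(len(lr), -1), axis=0)]
            )
            S2 = S2 + self.G_at_events[:, None, None] * preXX[self.pos_late].reshape(
                -1, self.p, self.p
            )
        return S0, S1, S2


def _partial_likelihood(beta, sums_engine, fail_X, fail_counts):
    """Breslow log-likelihood, score and information at beta.

    fail_X: (E, p) sum of covariates of subjects failing at each event time;
    fail_counts: (E,) number failing (ties processed as one grid point).
    """
    S0, S1, S2 = sums_engine.sums(beta)
    if np.any(S0 <= 0):
        raise FitError("empty risk set at an event time")
    ll = float(np.sum(fail_X @ beta) - np.sum(fail_counts * np.log(S0)))
    xbar = S1 / S0[:, None]
    score = fail_X.sum(axis=0) - (fail_counts[:, None] * xbar).sum(axis=0)
    v = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    info = (fail_counts[:, None, None] * v).sum(axis=0)
    return ll, score, info


def _newton(sums_engine, fail_X, fail_counts, p):
    beta = np.zeros(p)
    ll, score, info = _partial_likelihood(beta, sums_engine, fail_X, fail_counts)
    messages: list[str] = []
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise FitError(f"singular information matrix: {e}") from None
        # step-halving: never let the log-likelihood decrease
        for _ in range(30):
            cand = beta + step
            try:
                ll_new, score_new, info_new = _partial_likelihood(
                    cand, sums_engine, fail_X, fail_counts
                )
            except FloatingPointError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            messages.append("step-halving failed to improve the likelihood")
            break
        rel = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if rel < LL_RELTOL:
            converged = True
            break
    if np.any(np.abs(beta) > COEF_CAP):
        beta = np.clip(beta, -COEF_CAP, COEF_CAP)
        ll, score, info = _partial_likelihood(beta, sums_engine, fail_X, fail_counts)
        messages.append(
            "monotone likelihood suspected (complete separation); coefficient capped"
        )
        warnings.warn(messages[-1], stacklevel=3)
        converged = False
    if not converged and not messages:
        raise FitError(f"Newton-Raphson did not converge in {MAX_ITER} iterations")
    return beta, ll, score, info, converged, it, messages


def _as_counting_process(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    if isinstance(data, CountingProcessData):
        d = data.data
        return (
            d["start"].to_numpy(float),
            d["stop"].to_numpy(float),
            d["status"].to_numpy(int),
            d,
        )
    if isinstance(data, CohortTable):
        d = data.data
        n = len(d)
        return (
            np.zeros(n),
            d["time"].to_numpy(float),
            d["cause"].to_numpy(int),
            d,
        )
    raise TypeError(f"unsupported data type {type(data)!r}")


def _fail_groups(stop, status, X, cause):
    is_event = status == cause
    if not np.any(is_event):
        raise FitError(f"no events of cause {cause}")
    ev_times = np.unique(stop[is_event])
    grp = np.searchsorted(ev_times, stop[is_event])
    p = X.shape[1]
    fail_X = np.zeros((ev_times.size, p))
    np.add.at(fail_X, grp, X[is_event])
    fail_counts = np.bincount(grp, minlength=ev_times.size).astype(float)
    return ev_times, fail_X, fail_counts, int(is_event.sum())


def fit_cox(data, covariates: list[str], cause: int = 1) -> RegressionFit:
    """Cause-specific Cox model (Breslow ties, Newton-Raphson).

    Events of the other cause are censored at their failure time; accepts a
    subject-level :class:`CohortTable` or counting-process rows with
    time-updated covariates.
    """
    start, stop, status, d = _as_counting_process(data)
    X = d[covariates].to_numpy(float)
    ev_times, fail_X, fail_counts, n_events = _fail_groups(stop, status, X, cause)
    engine = _RiskSums(start, stop, X, ev_times)
    beta, ll, score, info, converged, it, msgs = _newton(
        engine, fail_X, fail_counts, X.shape[1]
    )
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return RegressionFit(
        covariates=list(covariates),
        coef=beta,
        se=se,
        loglik=ll,
        n_events=n_events,
        kind="cox_cause_specific",
        cause=cause,
        converged=converged,
        n_iter=it,
        messages=msgs,
    )


def _fine_gray_engine(times, causes, X, cause):
    """Risk-set engine + failure groups for the subdistribution model."""
    other = 2 if cause == 1 else 1
    ev_times, fail_X, fail_counts, n_events = _fail_groups(
        times, causes, X, cause
    )
    G = censoring_survival(times, causes)
    if float(G(ev_times[-1])) <= 0:
        warnings.warn(
            "censoring survival reaches 0 before the last event; "
            "late risk-set contributions truncated",
            stacklevel=3,
        )
    late_idx = np.flatnonzero(causes == other)
    engine = _RiskSums(
        np.zeros_like(times), times, X, ev_times, late_idx=late_idx, G=G
    )
    return engine, ev_times, fail_X, fail_counts, n_events


def _score_residuals(beta, engine, times, causes, X, cause):
    """Per-subject score contributions U_i for the sandwich variance.

    U_i = sum_j (x_i - xbar(t_j)) [dN_i(t_j) - w_i(t_j) Y_i(t_j) r_i dL0(t_j)].
    The censoring-weight estimation term is ignored (documented
    approximation); O(E n) but only run once at convergence.
    """
    other = 2 if cause == 1 else 1
    S0, S1, _ = engine.sums(beta)
    ev = engine.event_times
    xbar = S1 / S0[:, None]
    is_event = causes == cause
    ev_counts = np.bincount(
        np.searchsorted(ev, times[is_event]), minlength=ev.size
    ).astype(float)
    dL0 = ev_counts / S0
    r = np.exp(X @ beta)
    n, p = X.shape
    U = np.zeros((n, p))
    # event part
    j_of = np.searchsorted(ev, times[is_event])
    U[is_event] = X[is_event] - xbar[j_of]
    # compensator part
    G = engine.G_at_events if engine.late_idx.size else None
    late = causes == other
    g_at_own = np.ones(n)
    if engine.late_idx.size:
        g_at_own[engine.late_idx] = engine.G_at_stop
    for j, t in enumerate(ev):
        at_risk = times >= t
        w = at_risk.astype(float)
        if engine.late_idx.size:
            tail = late & (times < t)
            if np.any(tail):
                with np.errstate(divide="ignore", invalid="ignore"):
                    w[tail] = np.where(
                        g_at_own[tail] > 0, G[j] / g_at_own[tail], 0.0
                    )
        active = w > 0
        U[active] -= (
            (w[active] * r[active] * dL0[j])[:, None] * (X[active] - xbar[j])
        )
    return U


def fit_fine_gray(
    data: CohortTable, covariates: list[str], cause: int = 1, variance: str = "sandwich"
) -> RegressionFit:
    """Fine-Gray subdistribution-hazards regression.

    Subjects failing from the competing cause stay in the cause-``cause``
    risk set beyond their failure time, down-weighted by
    w_i(t) = G(t)/G(min(T_i, t)) with G the censoring-distribution
    Kaplan-Meier.  Variance: model-based inverse information
    (``variance="model"``) or the sandwich I^{-1} (sum U_i U_i') I^{-1}
    (``variance="sandwich"``, default); both ignore the variability of the
    estimated censoring weights.
    """
    if not isinstance(data, CohortTable):
        raise TypeError("fit_fine_gray expects subject-level CohortTable data")
    d = data.data
    times = d["time"].to_numpy(float)
    causes_arr = d["cause"].to_numpy(int)
    X = d[covariates].to_numpy(float)
    engine, ev_times, fail_X, fail_counts, n_events = _fine_gray_engine(
        times, causes_arr, X, cause
    )
    beta, ll, score, info, converged, it, msgs = _newton(
        engine, fail_X, fail_counts, X.shape[1]
    )
    info_inv = np.linalg.inv(info)
    if variance == "sandwich":
        U = _score_residuals(beta, engine, times, causes_arr, X, cause)
        meat = U.T @ U
        cov = info_inv @ meat @ info_inv
        se = np.sqrt(np.diag(cov))
    elif variance == "model":
        se = np.sqrt(np.diag(info_inv))
    else:
        raise ValueError(f"unknown variance method {variance!r}")
    return RegressionFit(
        covariates=list(covariates),
        coef=beta,
        se=se,
        loglik=ll,
        n_events=n_events,
        kind="fine_gray",
        cause=cause,
        converged=converged,
        n_iter=it,
        messages=msgs,
    )


def gray_test(times, causes, group, cause: int = 1) -> GrayTestResult:
    """Compare cumulative incidence between groups (competing-risks log-rank
    analogue): the score test of the Fine-Gray model with group indicators,
    evaluated at the null.  df = number of groups - 1.
    """
    times = np.asarray(times, dtype=float)
    causes_arr = np.asarray(causes, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    counts = [(group == g).sum() for g in levels]
    if min(counts) == 0:
        raise ValueError("a group has zero subjects")
    X = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    engine, ev_times, fail_X, fail_counts, _ = _fine_gray_engine(
        times, causes_arr, X, cause
    )
    _, score, info = _partial_likelihood(
        np.zeros(X.shape[1]), engine, fail_X, fail_counts
    )
    try:
        stat = float(score @ np.linalg.solve(info, score))
    except np.linalg.LinAlgError as e:
        raise FitError(f"singular information at the null: {e}") from None
    df = int(levels.size - 1)
    return GrayTestResult(statistic=max(stat, 0.0), df=df, p=float(stats.chi2.sf(stat, df)))


def gray_test_permutation(
    times, causes, group, cause: int = 1, n_perm: int = 2000, seed: int = 0
) -> GrayTestResult:
    """Permutation reference for :func:`gray_test`: the same score statistic
    with group labels permuted; p = (1 + #{stat* >= stat}) / (n_perm + 1)."""
    rng = np.random.default_rng(seed)
    obs = gray_test(times, causes, group, cause=cause)
    group = np.asarray(group)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        s = gray_test(times, causes, perm, cause=cause).statistic
        if s >= obs.statistic:
            count += 1
    return GrayTestResult(
        statistic=obs.statistic, df=obs.df, p=(1 + count) / (n_perm + 1)
    )


def bootstrap_se(
    data: CohortTable,
    covariates: list[str],
    cause: int,
    kind: str = "fine_gray",
    n_boot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Subject-resampling bootstrap standard errors (cross-check for the
    sandwich approximation)."""
    rng = np.random.default_rng(seed)
    d = data.data
    n = len(d)
    coefs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = CohortTable(d.iloc[idx].reset_index(drop=True).assign(
            subject_id=[f"B{i}" for i in range(n)]
        ))
        try:
            if kind == "fine_gray":
                fit = fit_fine_gray(boot, covariates, cause=cause, variance="model")
            else:
                fit = fit_cox(boot, covariates, cause=cause)
        except FitError:
            continue
        coefs.append(fit.coef)
    if len(coefs) < max(10, n_boot // 4):
        raise FitError("too many bootstrap resamples failed to fit")
    return np.std(np.asarray(coefs), axis=0, ddof=1)
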