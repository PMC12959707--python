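"""Nonparametric estimators for right-censored competing-risks data.

Kaplan-Meier product-limit survival, Nelson-Aalen cumulative hazard, the
censoring-distribution Kaplan-Meier (needed for inverse-probability-of-
censoring weights), and the Aalen-Johansen cumulative incidence function.

Tie convention throughout: events precede censorings at the same time, so
subjects censored at t are still in the risk set for deaths at t, while the
censoring-distribution estimator removes same-time deaths from its risk set
before counting censorings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StepFunction:
    """Right-continuous step function on [0, inf).

    ``times`` are the (strictly increasing) jump times; ``values`` the value
    at and after each jump.  Evaluation before the first jump returns
    ``initial`` (1 for survival curves, 0 for cumulative quantities).
    """

    times: np.ndarray
    values: np.ndarray
    variances: np.ndarray | None = None
    initial: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.initial)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side=side) - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.initial)
        return out if out.ndim else float(out)

    def __call__(self, t) -> np.ndarray | float:
        return self._eval(t, "right")

    def before(self, t) -> np.ndarray | float:
        """Left-limit evaluation: value just before t."""
        return self._eval(t, "left")


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence for one cause."""

    cause: int
    step: StepFunction
    at_risk: np.ndarray = field(default_factory=lambda: np.array([]))

    def __call__(self, t):
        return self.step(t)


def _event_table(times, causes):
    """Unique event/censoring times with counts per cause and risk sets."""
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    ut, inv = np.unique(times, return_inverse=True)
    n = times.size
    # risk set just before t: subjects with time >= t
    n_at_risk = n - np.searchsorted(np.sort(times), ut, side="left")
    counts = {
        k: np.bincount(inv[causes == k], minlength=ut.size) for k in (0, 1, 2)
    }
    return ut, n_at_risk, counts


def kaplan_meier(times, causes, event_rule=(1, 2)) -> StepFunction:
    """Product-limit survival estimator with Greenwood variance.

    ``event_rule`` lists the cause codes counted as events; the default
    treats death from either cause as the event (overall survival).
    """
    ut, n_risk, counts = _event_table(times, causes)
    d = sum(counts[k] for k in event_rule)
    keep = d > 0
    tj, nj, dj = ut[keep], n_risk[keep], d[keep]
    surv = np.cumprod(1.0 - dj / nj)
    # Greenwood: var(S) = S^2 * sum d/(n(n-d)); terms with n==d give S=0
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(nj > dj, dj / (nj * (nj - dj)), np.inf))
        var = np.where(surv > 0, surv**2 * gw, 0.0)
    return StepFunction(tj, surv, variances=var, initial=1.0)


def nelson_aalen(times, causes, event_rule=(1, 2)) -> StepFunction:
    """Nelson-Aalen cumulative hazard: sum d_j/n_j, variance sum d_j/n_j^2."""
    ut, n_risk, counts = _event_table(times, causes)
    d = sum(counts[k] for k in event_rule)
    keep = d > 0
    tj, nj, dj = ut[keep], n_risk[keep], d[keep]
    haz = np.cumsum(dj / nj)
    var = np.cumsum(dj / nj**2)
    return StepFunction(tj, haz, variances=var, initial=0.0)


def censoring_survival(times, causes) -> StepFunction:
    """Kaplan-Meier estimate G of the censoring distribution.

    Censorings are the "events"; deaths at the same time leave the risk set
    first (events precede censorings), so the factor at a tied time is
    1 - c_j/(n_j - d_j).
    """
    ut, n_risk, counts = _event_table(times, causes)
    c = counts[0]
    d = counts[1] + counts[2]
    keep = c > 0
    tj, nj, cj, dj = ut[keep], n_risk[keep], c[keep], d[keep]
    denom = nj - dj
    surv = np.cumprod(1.0 - cj / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(denom > cj, cj / (denom * (denom - cj)), np.inf))
        var = np.where(surv > 0, surv**2 * gw, 0.0)
    return StepFunction(tj, surv, variances=var, initial=1.0)


def aalen_johansen_cif(times, causes, cause: int) -> CIFEstimate:
    """Aalen-Johansen cumulative incidence for one cause.

    CIF_k(t) = sum over event times t_j <= t of S(t_j-) d_kj / n_j, with S
    the all-cause Kaplan-Meier on the same data.  The pointwise variance is
    the Aalen-type counting-process estimator

        var(F_k(t)) = sum_j [F_k(t) - F_k(t_j)]^2 d_j / (n_j (n_j - d_j))
                    + sum_j S(t_j-)^2 (n_j - d_kj)/n_j * d_kj / n_j^2
                    - 2 sum_j [F_k(t) - F_k(t_j)] S(t_j-) d_kj / n_j^2

    (all-cause d_j in the first term), the form used by standard survival
    software for competing-risks curves.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    ut, n_risk, counts = _event_table(times, causes)
    d_all = counts[1] + counts[2]
    keep = d_all > 0
    tj, nj = ut[keep], n_risk[keep]
    dj = d_all[keep]
    dkj = counts[cause][keep]
    if tj.size == 0:
        # no deaths at all: CIF identically zero with a single sentinel jump
        return CIFEstimate(cause, StepFunction(np.array([np.max(ut)]), np.array([0.0]),
                                               variances=np.array([0.0]), initial=0.0),
                           at_risk=np.array([int(n_risk[0])]))
    s_prev = np.concatenate([[1.0], np.cumprod(1.0 - dj / nj)[:-1]])  # S(t_j-)
    jumps = s_prev * dkj / nj
    cif = np.cumsum(jumps)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(nj > dj, dj / (nj * (nj - dj)), 0.0)
    b = s_prev**2 * (nj - dkj) / nj * dkj / nj**2
    c = s_prev * dkj / nj**2
    # var at t_i needs sums over j<=i involving F(t_i)-F(t_j)
    F = cif
    csum_a = np.cumsum(a)
    csum_aF = np.cumsum(a * F)
    csum_aF2 = np.cumsum(a * F**2)
    term1 = F**2 * csum_a - 2 * F * csum_aF + csum_aF2
    csum_b = np.cumsum(b)
    csum_c = np.cumsum(c)
    csum_cF = np.cumsum(c * F)
    term3 = -2 * (F * csum_c - csum_cF)
    var = term1 + csum_b + term3
    return CIFEstimate(
        cause,
        StepFunction(tj, cif, variances=np.maximum(var, 0.0), initial=0.0),
        at_risk=nj.astype(int),
    )


def survival_ci(step: StepFunction, alpha: float = 0.05, method: str = "loglog"):
    """Pointwise confidence band for a survival step function.

    The log(-log) transform keeps the band inside (0, 1); this is the
    default used for the overall-survival rates the package reports.
    """
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    s = step.values
    var = step.variances
    lo = np.full_like(s, np.nan)
    hi = np.full_like(s, np.nan)
    ok = (s > 0) & (s < 1) & np.isfinite(var)
    if method == "loglog":
        se_cll = np.sqrt(var[ok]) / (s[ok] * np.abs(np.log(s[ok])))
        lo[ok] = s[ok] ** np.exp(z * se_cll)
        hi[ok] = s[ok] ** np.exp(-z * se_cll)
    elif method == "plain":
        half = z * np.sqrt(var[ok])
        lo[ok] = np.clip(s[ok] - half, 0, 1)
        hi[ok] = np.clip(s[ok] + half, 0, 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return lo, hi


def to_frame(step: StepFunction, label: str = "estimate"):
    """Tidy export: one row per jump time."""
    import pandas as pd

    d = {"time": step.times, label: step.values}
    if step.variances is not None:
        d["variance"] = step.variances
    return pd.DataFrame(d)
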