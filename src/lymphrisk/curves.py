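"""Time-varying effect curves beta(t) and their summaries.

The additive model yields cumulative coefficients B(t); the instantaneous
absolute risk difference per unit covariate is its derivative, approximated
by first differences beta_raw = dB/dt on the event-time grid and smoothed
with LOESS (local linear regression, tricube weights, span 0.35, no
robustness iterations).  Each smoothed curve is summarized by

* t_peak        — time of the maximum smoothed effect;
* t_zero_cross  — first time the smoothed effect crosses from positive
                  to <= 0 (absent if it never does);
* plateau       — the longest continuous post-peak segment in which the
                  centred 7-point moving average of |beta(t)| stays below a
                  data-adaptive threshold
                  max{ z_{1-a/2} * MAD(raw beta - smoothed beta),
                       eps_frac * max |beta(t)| }
                  with alpha = 0.01 and eps_frac = 0.03 by default.

The MAD is the raw (unscaled) median absolute deviation about the median of
the residuals; windows truncated at the grid ends are excluded from plateau
eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .additive import CumulativeCoefficients

DEFAULT_SPAN = 0.35
DEFAULT_ALPHA = 0.01
DEFAULT_EPS_FRAC = 0.03
MA_WINDOW = 7


@dataclass
class BetaCurve:
    """Instantaneous effect curve of one covariate on the event-time grid.

    ``times`` are the right endpoints of the grid intervals; ``beta_raw``
    the per-interval difference quotients; ``beta_smooth`` the LOESS-
    smoothed values at the same times (None until smoothing is applied).
    """

    times: np.ndarray
    beta_raw: np.ndarray
    beta_smooth: np.ndarray | None = None
    covariate: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.beta_raw = np.asarray(self.beta_raw, dtype=float)
        if self.times.shape != self.beta_raw.shape:
            raise ValueError("times and beta_raw must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.beta_smooth is not None:
            self.beta_smooth = np.asarray(self.beta_smooth, dtype=float)


@dataclass
class CurveSummary:
    """t_peak / t_zero-cross / plateau summary of one beta(t) curve."""

    covariate: str
    t_peak: float
    t_zero_cross: float | None
    plateau_start: float | None
    plateau_end: float | None
    threshold: float
    ma_window: int = MA_WINDOW
    notes: str = ""


def derive_beta(cc: CumulativeCoefficients, covariate: str) -> BetaCurve:
    """First-difference quotient beta_raw(t_j) = dB/dt on the event grid.

    Indexed at the right endpoint of each interval; the first interval runs
    from 0 (where B = 0 by construction) to the first event time.
    """
    if cc.n_times < 2:
        raise ValueError("need at least 2 grid points to differentiate")
    t = cc.grid
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate grid times; merge ties in fit_aalen first")
    B = cc.column(covariate)
    t0 = np.concatenate([[0.0], t])
    B0 = np.concatenate([[0.0], B])
    beta = np.diff(B0) / np.diff(t0)
    return BetaCurve(times=t, beta_raw=beta, covariate=covariate)


def loess_smooth(curve: BetaCurve, span: float = DEFAULT_SPAN) -> BetaCurve:
    """LOESS smoothing: local linear fit at every grid time.

    Each fit uses the ceil(span*n) nearest neighbours, tricube weights on
    distance scaled by the window radius, and no robustness iterations, so
    exactly linear inputs are reproduced exactly.
    """
    x = curve.times
    y = curve.beta_raw
    n = x.size
    k = int(np.ceil(span * n))
    if n < max(4, k):
        raise ValueError(f"need at least max(4, ceil(span*n)) = {max(4, k)} points")
    k = max(k, 2)
    smooth = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        # window radius = k-th smallest distance
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            smooth[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w @ x) / sw
        ym = (w @ y) / sw
        dx = x - xm
        sxx = w @ (dx * dx)
        if sxx <= 1e-12 * (x[-1] - x[0]) ** 2:
            smooth[i] = ym
        else:
            b = (w @ (dx * y)) / sxx
            smooth[i] = ym + b * (x[i] - xm)
    return BetaCurve(
        times=x.copy(), beta_raw=y.copy(), beta_smooth=smooth, covariate=curve.covariate
    )


def adaptive_threshold(
    curve: BetaCurve, alpha: float = DEFAULT_ALPHA, eps_frac: float = DEFAULT_EPS_FRAC
) -> float:
    """Data-adaptive plateau threshold.

    max( z_{1-alpha/2} * MAD(beta_raw - beta_smooth),
         eps_frac * max|beta_smooth| )
    with the MAD unscaled (no normal-consistency constant).
    """
    if curve.beta_smooth is None:
        raise ValueError("smooth the curve first")
    resid = curve.beta_raw - curve.beta_smooth
    mad = float(np.median(np.abs(resid - np.median(resid))))
    z = float(stats.norm.ppf(1 - alpha / 2))
    return max(z * mad, eps_frac * float(np.max(np.abs(curve.beta_smooth))))


def moving_average(values: np.ndarray, window: int = MA_WINDOW) -> np.ndarray:
    """Centred moving average; positions whose window is truncated by the
    grid ends are NaN (excluded from plateau eligibility)."""
    n = values.size
    half = window // 2
    out = np.full(n, np.nan)
    if n >= window:
        kernel = np.ones(window) / window
        out[half : n - half] = np.convolve(values, kernel, mode="valid")
    return out


def summarize_curve(
    curve: BetaCurve,
    alpha: float = DEFAULT_ALPHA,
    eps_frac: float = DEFAULT_EPS_FRAC,
    ma_on: str = "smooth",
    max_time: float | None = None,
) -> CurveSummary:
    """Summarize a smoothed beta(t) curve by peak, zero-cross and plateau.

    t_peak: grid time of the maximum smoothed value (first occurrence on
    ties).  t_zero_cross: first grid time, after the curve has been strictly
    positive, at which it is <= 0.  Plateau: among maximal runs of
    consecutive post-peak grid points where the centred ``ma_window``-point
    moving average of |beta| is strictly below the adaptive threshold, the
    run of greatest time length (first on ties); absent when no eligible
    run exists.  ``ma_on`` selects the smoothed (default) or raw curve for
    the moving average; ``max_time`` optionally truncates the grid first
    (late, sparse-risk-set oscillations can otherwise dominate).
    """
    if curve.beta_smooth is None:
        raise ValueError("smooth the curve first")
    t = curve.times
    s = curve.beta_smooth
    raw = curve.beta_raw
    if max_time is not None:
        keep = t <= max_time
        t, s, raw = t[keep], s[keep], raw[keep]
        curve = BetaCurve(t, raw, beta_smooth=s, covariate=curve.covariate)
    notes = []

    i_peak = int(np.argmax(s))
    t_peak = float(t[i_peak])

    t_zero = None
    been_positive = False
    for i in range(t.size):
        if s[i] > 0:
            been_positive = True
        elif been_positive and s[i] <= 0:
            t_zero = float(t[i])
            break

    threshold = adaptive_threshold(curve, alpha=alpha, eps_frac=eps_frac)

    plateau_start = plateau_end = None
    if t.size < MA_WINDOW:
        notes.append("fewer than 7 points; plateau not evaluated")
    else:
        basis = s if ma_on == "smooth" else raw
        ma = moving_average(np.abs(basis), MA_WINDOW)
        eligible = (np.arange(t.size) > i_peak) & np.isfinite(ma) & (ma < threshold)
        best_len = -1.0
        i = 0
        while i < t.size:
            if eligible[i]:
                j = i
                while j + 1 < t.size and eligible[j + 1]:
                    j += 1
                length = t[j] - t[i]
                if j - i + 1 >= MA_WINDOW and length > best_len:
                    best_len = length
                    plateau_start, plateau_end = float(t[i]), float(t[j])
                i = j + 1
            else:
                i += 1
    return CurveSummary(
        covariate=curve.covariate,
        t_peak=t_peak,
        t_zero_cross=t_zero,
        plateau_start=plateau_start,
        plateau_end=plateau_end,
        threshold=threshold,
        ma_window=MA_WINDOW,
        notes="; ".join(notes),
    )


def beta_pipeline(
    cc: CumulativeCoefficients,
    covariate: str,
    span: float = DEFAULT_SPAN,
    alpha: float = DEFAULT_ALPHA,
    eps_frac: float = DEFAULT_EPS_FRAC,
    max_time: float | None = None,
) -> tuple[BetaCurve, CurveSummary]:
    """Full chain: differentiate B(t), smooth, summarize."""
    curve = loess_smooth(derive_beta(cc, covariate), span=span)
    summary = summarize_curve(curve, alpha=alpha, eps_frac=eps_frac, max_time=max_time)
    return curve, summary
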