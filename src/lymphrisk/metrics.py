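"""Discrimination metrics: Harrell's concordance index for survival scores,
with a competing-risks (subdistribution) comparability rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConcordanceResult:
    c_index: float
    concordant: float
    discordant: float
    tied_risk: float
    n_comparable: float


def harrell_c(
    risk, times, causes, cause: int = 1, competing_rule: str = "subdistribution"
) -> ConcordanceResult:
    """Harrell's c-index for cause-``cause`` failure.

    A pair (i, j) with subject i failing from the target cause at t_i is
    comparable when t_j > t_i, or — under the default subdistribution rule —
    when j failed from the competing cause at any time (j can never fail
    from the target cause, so it stays "at risk" for it).  The pair is
    concordant when risk_i > risk_j; ties in risk count 1/2.  Pairs where
    both subjects fail from the target cause at the same time are not
    comparable.  ``competing_rule="cause_specific"`` drops the extra
    competing-failure pairs.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    causes_arr = np.asarray(causes, dtype=int)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    if competing_rule not in ("subdistribution", "cause_specific"):
        raise ValueError(f"unknown competing_rule {competing_rule!r}")
    other = 2 if cause == 1 else 1

    is_k = causes_arr == cause
    idx_i = np.flatnonzero(is_k)
    if idx_i.size == 0:
        raise ValueError("no comparable pairs: no events of the target cause")

    t_i = times[idx_i][:, None]
    r_i = risk[idx_i][:, None]
    later = times[None, :] > t_i
    comparable = later.copy()
    if competing_rule == "subdistribution":
        comparable |= (causes_arr == other)[None, :] & ~later
    # i may not be paired with itself, and pairs of two cause-k failures are
    # counted once, anchored at the earlier failure
    comparable[:, idx_i] &= times[idx_i][None, :] > t_i
    np.fill_diagonal(comparable[:, idx_i], False)

    diff = r_i - risk[None, :]
    conc = float(np.sum(comparable & (diff > 0)))
    disc = float(np.sum(comparable & (diff < 0)))
    tied = float(np.sum(comparable & (diff == 0)))
    n_comp = conc + disc + tied
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return ConcordanceResult(
        c_index=(conc + 0.5 * tied) / n_comp,
        concordant=conc,
        discordant=disc,
        tied_risk=tied,
        n_comparable=n_comp,
    )
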