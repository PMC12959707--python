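"""Plot helpers: overall-survival / cumulative-incidence panels and
smoothed beta(t) overlays (one line per covariate, independent y-scales
when faceted)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .additive import CumulativeCoefficients
from .cohort import CohortTable, assign_groups
from .curves import beta_pipeline
from .nonparametric import aalen_johansen_cif, kaplan_meier


def _step_plot(ax, step, label=None, **kw):
    t = np.concatenate([[0.0], step.times])
    v = np.concatenate([[step.initial], step.values])
    ax.step(t, v, where="post", label=label, **kw)


def plot_cif_panel(cohort: CohortTable, path) -> None:
    """Overall survival plus per-group cumulative incidence of both causes."""
    groups = assign_groups(cohort)
    times = cohort.data["time"].to_numpy(float)
    causes = cohort.data["cause"].to_numpy(int)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))

    _step_plot(axes[0], kaplan_meier(times, causes), label="all subjects")
    axes[0].set(title="Overall survival", xlabel="years", ylabel="S(t)", ylim=(0, 1.02))
    axes[0].legend()

    for ax, cause, name in ((axes[1], 1, "progression death"), (axes[2], 2, "non-lymphoma death")):
        for g in np.unique(groups):
            mask = (groups == g).to_numpy()
            if (causes[mask] == cause).sum() == 0:
                continue
            _step_plot(ax, aalen_johansen_cif(times[mask], causes[mask], cause).step, label=g)
        ax.set(title=f"Cumulative incidence: {name}", xlabel="years", ylabel="CIF(t)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_overlay(
    cc: CumulativeCoefficients, covariates, path, span: float = 0.35
) -> None:
    """Smoothed instantaneous-effect overlays beta(t) per covariate."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cov in covariates:
        try:
            curve, _ = beta_pipeline(cc, cov, span=span)
        except ValueError:
            continue
        ax.plot(curve.times, curve.beta_smooth, label=cov)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set(xlabel="years since diagnosis", ylabel="beta(t), absolute risk difference / year")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
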