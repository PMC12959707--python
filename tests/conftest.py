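"""Shared fixtures and small data builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lymphrisk.cohort import CohortTable

# property tests must fail (or pass) reproducibly across runs
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_cohort(times, causes, **columns) -> CohortTable:
    """Subject-level cohort from plain arrays; defaults to all-FL subtype."""
    times = np.asarray(times, dtype=float)
    n = times.size
    d = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "time": times,
            "cause": np.asarray(causes, dtype=int),
        }
    )
    if not any(c.startswith("subtype_") for c in columns):
        d["subtype_fl"] = 1
    for name, values in columns.items():
        d[name] = values
    return CohortTable(d)


def competing_exponential(
    n, seed, lam1=0.15, lam2=0.10, beta1=0.0, beta2=0.0, censor=(0.5, 8.0)
):
    """Two competing exponential causes with one binary covariate.

    Cause-specific hazards lam_k * exp(beta_k * x); uniform censoring.
    Returns (times, causes, x).
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    with np.errstate(divide="ignore"):
        t1 = rng.exponential(1.0, n) / (lam1 * np.exp(beta1 * x))
        t2 = rng.exponential(1.0, n) / (lam2 * np.exp(beta2 * x))
    c = rng.uniform(*censor, n)
    t = np.minimum(np.minimum(t1, t2), c)
    cause = np.where(t == c, 0, np.where(t1 <= t2, 1, 2))
    return t, cause, x


@pytest.fixture
def small_cohort() -> CohortTable:
    """10 valid subjects covering both causes, censoring and exposures."""
    rng = np.random.default_rng(7)
    times = rng.uniform(0.5, 12.0, 10).round(2)
    causes = [0, 1, 2, 0, 1, 0, 2, 0, 1, 0]
    c = make_cohort(times, causes, age_gt60=rng.integers(0, 2, 10))
    c.data.loc[0, "sm_onset"] = times[0] / 2
    c.data.loc[3, "ht_onset"] = times[3] / 3
    return c
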