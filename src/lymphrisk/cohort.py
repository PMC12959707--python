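"""Cohort data model: subject-level records, validation, counting-process expansion.

The analysis operates on one row per subject: follow-up time in years from
diagnosis, a cause code (0 = censored, 1 = lymphoma-progression death,
2 = non-lymphoma death), binary baseline covariates, and optional onset
times (years from diagnosis) for time-updated exposures — secondary
malignancy (sm), histologic transformation (ht) and COVID-19 (covid).
Time-updated exposures are expanded into counting-process rows
(start, stop, status) before regression or additive-hazards fitting.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: binary baseline covariates, in canonical order
COVARIATES = [
    "age_gt60",
    "male",
    "subtype_fl",
    "subtype_enmzl",
    "subtype_nmzl",
    "subtype_mcl",
    "nodes_gt4",
    "bm_involve",
    "spleen",
    "pleural_effusion",
    "ldh_elev",
    "hb_lt12",
    "stage34",
]

SUBTYPES = ["subtype_fl", "subtype_enmzl", "subtype_nmzl", "subtype_mcl"]

#: time-updated exposures; onset columns are "<name>_onset"
EXPOSURES = ["sm", "ht", "covid"]

MANDATORY_COLUMNS = ["subject_id", "time", "cause"]

#: administrative maximum follow-up, years
MAX_FOLLOWUP = 13.0

CAUSE_CENSORED = 0
CAUSE_PROGRESSION = 1  # lymphoma-progression death (CIP event)
CAUSE_NONLYMPHOMA = 2  # non-lymphoma death (NLM event)


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong type."""


class RecordError(ValueError):
    """A record violates a cohort invariant."""


@dataclass(frozen=True)
class Violation:
    subject_id: str
    fieldname: str
    rule: str

    def __str__(self) -> str:
        return f"subject {self.subject_id!r}: {self.fieldname}: {self.rule}"


@dataclass
class CohortTable:
    """Subject-level cohort: one row per subject.

    ``data`` holds columns ``subject_id``, ``time`` (years > 0), ``cause``
    (0/1/2), the binary covariates in :data:`COVARIATES`, and onset columns
    ``sm_onset``/``ht_onset``/``covid_onset`` (NaN = never exposed).
    Columns not understood by the model are preserved in ``metadata``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        for exp in EXPOSURES:
            col = f"{exp}_onset"
            if col not in self.data.columns:
                self.data[col] = np.nan
        for cov in COVARIATES:
            if cov not in self.data.columns:
                self.data[cov] = 0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def covariate_matrix(self, covariates: list[str] | None = None) -> np.ndarray:
        cols = covariates if covariates is not None else COVARIATES
        return self.data[cols].to_numpy(dtype=float)

    def exposure_present(self, exposure: str) -> pd.Series:
        return self.data[f"{exposure}_onset"].notna()


@dataclass
class CountingProcessData:
    """Long-format rows (subject_id, start, stop, status, covariates).

    Exposure state columns (``sm``, ``ht``, ``covid``) are 0/1 indicators of
    the current state on each (start, stop] interval; only the last row of a
    subject may carry a non-zero status.
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def arrays(self, covariates: list[str]) -> tuple[np.ndarray, ...]:
        """(start, stop, status, X) as numpy arrays for the fitters."""
        d = self.data
        return (
            d["start"].to_numpy(float),
            d["stop"].to_numpy(float),
            d["status"].to_numpy(int),
            d[covariates].to_numpy(float),
        )


def read_cohort(path, dialect: dict[str, str] | None = None) -> CohortTable:
    """Read a subject-level cohort CSV.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row, one row per subject.
    dialect : dict, optional
        Mapping from file column names to canonical names, for files using
        a different column dictionary.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    RecordError
        if a time/cause value cannot be parsed or a record violates a
        cohort invariant; the message names the subject and line.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    df["subject_id"] = df["subject_id"].astype(str)
    for col, caster in (("time", float), ("cause", int)):
        try:
            df[col] = df[col].astype(caster)
        except (ValueError, TypeError):
            for line, (sid, raw) in enumerate(zip(df["subject_id"], df[col]), start=2):
                try:
                    caster(raw)
                except (ValueError, TypeError):
                    raise RecordError(
                        f"subject {sid!r} (line {line}): unparseable {col} value {raw!r}"
                    ) from None

    known = set(MANDATORY_COLUMNS) | set(COVARIATES) | {f"{e}_onset" for e in EXPOSURES}
    extra = [c for c in df.columns if c not in known]
    meta = df[["subject_id", *extra]].copy() if extra else None
    cohort = CohortTable(df.drop(columns=extra), metadata=meta)

    violations = validate_cohort(cohort)
    if violations:
        raise RecordError(
            "invalid cohort: " + "; ".join(str(v) for v in violations[:10])
        )
    return cohort


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort back to the CSV exchange format."""
    cohort.data.to_csv(path, index=False)


def validate_cohort(cohort: CohortTable) -> list[Violation]:
    """Check every cohort invariant; returns one descriptor per violation.

    Never raises: an empty list means the cohort is valid.
    """
    d = cohort.data
    out: list[Violation] = []

    dup = d["subject_id"][d["subject_id"].duplicated()]
    for sid in dup.unique():
        out.append(Violation(str(sid), "subject_id", "duplicate subject_id"))

    for _, row in d.iterrows():
        sid = str(row["subject_id"])
        t = row["time"]
        if not np.isfinite(t) or t <= 0:
            out.append(Violation(sid, "time", f"time must be > 0, got {t}"))
        elif t > MAX_FOLLOWUP:
            out.append(
                Violation(sid, "time", f"time {t} exceeds max follow-up {MAX_FOLLOWUP}")
            )
        if row["cause"] not in (0, 1, 2):
            out.append(Violation(sid, "cause", f"cause must be 0/1/2, got {row['cause']}"))
        sub = [row.get(s, 0) for s in SUBTYPES]
        if sum(sub) != 1:
            out.append(Violation(sid, "subtype", "subtype not exclusive"))
        for cov in COVARIATES:
            v = row.get(cov, 0)
            if v not in (0, 1):
                out.append(Violation(sid, cov, f"indicator must be 0/1, got {v}"))
        for exp in EXPOSURES:
            onset = row.get(f"{exp}_onset", np.nan)
            if pd.notna(onset):
                if onset < 0:
                    out.append(
                        Violation(sid, f"{exp}_onset", f"onset must be >= 0, got {onset}")
                    )
                elif np.isfinite(t) and onset > t:
                    out.append(
                        Violation(sid, f"{exp}_onset", "exposure after follow-up end")
                    )
    return out


def expand_counting_process(
    cohort: CohortTable, exposures: list[str] | None = None
) -> CountingProcessData:
    """Split each subject at exposure onsets into (start, stop] rows.

    The exposure indicator is 0 before its onset and 1 at and after it.
    An onset at 0 means exposed from entry; an onset equal to the follow-up
    time would create a zero-length interval and is collapsed (no row).
    Total exposed person-time therefore equals sum(time - onset) over
    subjects with onset < time.
    """
    if exposures is None:
        exposures = list(EXPOSURES)
    unknown = set(exposures) - set(EXPOSURES)
    if unknown:
        raise ValueError(f"unknown exposure(s): {sorted(unknown)}")

    d = cohort.data
    rows = []
    for _, row in d.iterrows():
        t = float(row["time"])
        onsets = {}
        for exp in exposures:
            o = row[f"{exp}_onset"]
            if pd.notna(o) and o < t:
                onsets[exp] = float(o)
        cuts = sorted({o for o in onsets.values() if o > 0.0})
        bounds = [0.0, *cuts, t]
        base = {c: row[c] for c in COVARIATES}
        for start, stop in zip(bounds[:-1], bounds[1:]):
            r = {"subject_id": row["subject_id"], "start": start, "stop": stop}
            r.update(base)
            for exp in exposures:
                r[exp] = int(exp in onsets and onsets[exp] <= start)
            r["status"] = int(row["cause"]) if stop == t else 0
            rows.append(r)
    cols = ["subject_id", "start", "stop", "status", *COVARIATES, *exposures]
    out = pd.DataFrame(rows, columns=cols)
    return CountingProcessData(out, covariates=[*COVARIATES, *exposures])


def collapse_counting_process(cp: CountingProcessData) -> pd.DataFrame:
    """Merge contiguous rows with identical covariate values (inverse of expand
    for subjects whose covariates never change)."""
    covcols = [c for c in cp.data.columns if c not in ("subject_id", "start", "stop", "status")]
    merged = []
    for sid, g in cp.data.groupby("subject_id", sort=False):
        g = g.sort_values("start")
        cur = g.iloc[0].to_dict()
        for _, row in g.iloc[1:].iterrows():
            if all(row[c] == cur[c] for c in covcols) and row["start"] == cur["stop"]:
                cur["stop"] = row["stop"]
                cur["status"] = row["status"]
            else:
                merged.append(cur)
                cur = row.to_dict()
        merged.append(cur)
    return pd.DataFrame(merged, columns=cp.data.columns).reset_index(drop=True)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("0." + "0" * ndigits), rounding=decimal.ROUND_HALF_UP
        )
    )


def percent(count: int, denom: int) -> float | None:
    """Table-style percentage: 100*count/denom, one decimal, half-up."""
    if denom == 0:
        return None
    return _round_half_up(100.0 * count / denom)


def assign_groups(cohort: CohortTable) -> pd.Series:
    """Three-way split: SM (sm_onset present), HT (ht_onset present, no SM),
    control (neither). SM takes priority when both exposures occurred."""
    sm = cohort.exposure_present("sm")
    ht = cohort.exposure_present("ht")
    grp = pd.Series("control", index=cohort.data.index)
    grp[ht & ~sm] = "HT"
    grp[sm] = "SM"
    return grp


def compare_2x2(table: np.ndarray, method: str = "auto") -> tuple[float, str]:
    """Group-comparison p-value for a 2x2 count table.

    ``method="auto"`` (default): chi-squared with continuity correction,
    switching to Fisher's exact test when any expected cell count is below
    5.  ``"chi2"`` and ``"fisher"`` force one test.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, "none"
    if method == "auto":
        expected = stats.contingency.expected_freq(table)
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "fisher":
        _, p = stats.fisher_exact(table)
        return float(p), "fisher"
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p), "chi2"


def compare_rxc(table: np.ndarray) -> tuple[float, str]:
    """Comparison p-value for an r x 2 table (e.g. subtype distribution).

    Fisher's exact test is only defined here for 2x2; larger sparse tables
    fall back to the chi-squared test with a note in the returned method.
    """
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=1) > 0
    table = table[keep]
    if table.shape[0] < 2:
        return np.nan, "none"
    if table.shape == (2, 2):
        return compare_2x2(table)
    expected = stats.contingency.expected_freq(table)
    method = "chi2" if (expected >= 5).all() else "chi2_small_cells"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), method


def cohort_summary(
    cohort: CohortTable,
    grouping: pd.Series | None = None,
    variables: list[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Characteristics table with per-group counts/percentages and pairwise tests.

    One row per binary variable (plus one per subtype level), columns per
    group with ``n`` and ``percent`` (one decimal, half-up), and pairwise
    p-values SM vs control, HT vs control, SM vs HT.  The subtype rows share
    a single 4x2 comparison per pair.  Empty groups report no percentage and
    their comparisons are skipped (p = NaN, method "none").
    """
    if grouping is None:
        grouping = assign_groups(cohort)
    if variables is None:
        variables = [c for c in COVARIATES if c not in SUBTYPES]
    d = cohort.data
    groups = ["SM", "HT", "control"]
    sizes = {g: int((grouping == g).sum()) for g in groups}
    pairs = [("SM", "control"), ("HT", "control"), ("SM", "HT")]

    records = []

    def pair_cols(pvals: dict) -> dict:
        return {f"p_{a}_vs_{b}": pvals.get((a, b), np.nan) for a, b in pairs}

    # subtype block: one joint comparison per pair
    sub_counts = {g: [int(d.loc[grouping == g, s].sum()) for s in SUBTYPES] for g in groups}
    sub_p = {}
    for a, b in pairs:
        if sizes[a] == 0 or sizes[b] == 0:
            sub_p[(a, b)] = np.nan
        else:
            tab = np.column_stack([sub_counts[a], sub_counts[b]])
            sub_p[(a, b)], _ = compare_rxc(tab)
    for i, s in enumerate(SUBTYPES):
        rec = {"variable": s}
        for g in groups:
            rec[f"n_{g}"] = sub_counts[g][i]
            rec[f"pct_{g}"] = percent(sub_counts[g][i], sizes[g])
        rec["n_total"] = int(d[s].sum())
        rec["pct_total"] = percent(int(d[s].sum()), len(d))
        rec.update(pair_cols(sub_p))
        records.append(rec)

    for var in variables:
        rec = {"variable": var}
        counts = {g: int(d.loc[grouping == g, var].sum()) for g in groups}
        for g in groups:
            rec[f"n_{g}"] = counts[g]
            rec[f"pct_{g}"] = percent(counts[g], sizes[g])
        rec["n_total"] = int(d[var].sum())
        rec["pct_total"] = percent(int(d[var].sum()), len(d))
        pvals = {}
        for a, b in pairs:
            if sizes[a] == 0 or sizes[b] == 0:
                pvals[(a, b)] = np.nan
                continue
            tab = np.array(
                [
                    [counts[a], sizes[a] - counts[a]],
                    [counts[b], sizes[b] - counts[b]],
                ]
            )
            pvals[(a, b)], _ = compare_2x2(tab, method=method)
        rec.update(pair_cols(pvals))
        records.append(rec)

    out = pd.DataFrame(records)
    out.attrs["group_sizes"] = sizes
    return out
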