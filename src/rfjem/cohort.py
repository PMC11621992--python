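"""Study cohort: participants, lifetime job histories, exclusions, reference dates.

Participants and job spells are carried as pandas DataFrames with the schemas
below.  Years are nullable integers (``Int64``); an empty year field means
"unknown" and is grounds for exclusion, not an error at load time.

``participants`` columns:
    pid, status {glioma, meningioma, control}, diagnosis_year (cases only),
    interview_year, age_group (5-year band label), sex {male, female},
    region, education {high_school_or_less, medium_technical, university,
    missing}, proxy (bool), grade {low, high, na}, preexisting_condition (bool)

``jobs`` columns:
    pid, start_year, end_year, isco88 (4-digit code, or empty/UNKNOWN),
    nonstandard (bool: housewife/husband, pensioner, training, imprisonment),
    source_reported (bool: participant reported RF-EMF source use in this job),
    source_uncertain (bool)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, OrphanSpellError, SchemaError

STATUSES = ("glioma", "meningioma", "control")
CASE_STATUSES = ("glioma", "meningioma")
EDUCATION_LEVELS = ("high_school_or_less", "medium_technical", "university", "missing")

PARTICIPANT_COLUMNS = [
    "pid", "status", "diagnosis_year", "interview_year", "age_group", "sex",
    "region", "education", "proxy", "grade", "preexisting_condition",
]
JOB_COLUMNS = [
    "pid", "start_year", "end_year", "isco88",
    "nonstandard", "source_reported", "source_uncertain",
]

#: Sentinel for an occupation that could not be coded.
UNKNOWN_CODE = "UNKNOWN"

#: Labels of the ordered exclusion criteria (applied first-match-wins).
EXCLUSION_CRITERIA = (
    "uncertain_source_or_no_history",
    "missing_education",
    "chronology",
    "nonstandard_only",
    "unknown_occupation",
)


@dataclass
class ExclusionLedger:
    """Audit trail of the ordered exclusion cascade, per status group.

    Conservation — initial = final + sum(excluded) in every group — is
    asserted on construction; each participant is counted at most once,
    under the first criterion it matches.
    """

    initial: dict[str, int]
    steps: list[tuple[str, dict[str, int]]] = field(default_factory=list)
    final: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for status in self.initial:
            removed = sum(counts.get(status, 0) for _, counts in self.steps)
            if self.initial[status] - removed != self.final.get(status, 0):
                raise DataError(
                    f"ledger not conserved for {status}: "
                    f"{self.initial[status]} - {removed} != {self.final.get(status, 0)}"
                )

    def excluded_total(self, status: str) -> int:
        return sum(counts.get(status, 0) for _, counts in self.steps)

    def to_frame(self) -> pd.DataFrame:
        statuses = list(self.initial)
        rows = [{"criterion": "initial", **self.initial}]
        rows += [{"criterion": label, **{s: c.get(s, 0) for s in statuses}}
                 for label, c in self.steps]
        rows.append({"criterion": "final", **{s: self.final.get(s, 0) for s in statuses}})
        return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def _as_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return s.astype(str).str.strip().str.lower().isin(["true", "1", "yes", "t"])


def load_cohort(participants_path, jobs_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the participant and job-spell tables.

    Job spells referencing a pid absent from the participant table raise
    :class:`OrphanSpellError`.  Chronologically incoherent spells are loaded
    as-is — flagging them is the exclusion stage's job, not the loader's.
    """
    pdf = pd.read_csv(participants_path, dtype={"pid": str})
    jdf = pd.read_csv(jobs_path, dtype={"pid": str, "isco88": str})
    _require_columns(pdf, PARTICIPANT_COLUMNS, "participants")
    _require_columns(jdf, JOB_COLUMNS, "jobs")

    pdf = pdf.copy()
    jdf = jdf.copy()
    for col in ("diagnosis_year", "interview_year"):
        pdf[col] = pd.to_numeric(pdf[col], errors="coerce").astype("Int64")
    for col in ("proxy", "preexisting_condition"):
        pdf[col] = _as_bool(pdf[col])
    for col in ("start_year", "end_year"):
        jdf[col] = pd.to_numeric(jdf[col], errors="coerce").astype("Int64")
    for col in ("nonstandard", "source_reported", "source_uncertain"):
        jdf[col] = _as_bool(jdf[col])

    bad_status = set(pdf["status"]) - set(STATUSES)
    if bad_status:
        raise SchemaError(f"unknown status values: {sorted(bad_status)}")
    pdf["education"] = pdf["education"].fillna("missing")
    bad_edu = set(pdf["education"]) - set(EDUCATION_LEVELS)
    if bad_edu:
        raise SchemaError(f"unknown education values: {sorted(bad_edu)}")
    if pdf["pid"].duplicated().any():
        dups = pdf.loc[pdf["pid"].duplicated(), "pid"].tolist()
        raise SchemaError(f"duplicate participant ids: {dups[:5]}")

    orphans = set(jdf["pid"]) - set(pdf["pid"])
    if orphans:
        raise OrphanSpellError(f"job spells reference unknown pids: {sorted(orphans)[:5]}")

    is_case = pdf["status"].isin(CASE_STATUSES)
    bad_chron = is_case & pdf["diagnosis_year"].notna() & pdf["interview_year"].notna() & (
        pdf["diagnosis_year"] > pdf["interview_year"]
    )
    if bad_chron.any():
        raise SchemaError(
            f"cases with diagnosis after interview: {pdf.loc[bad_chron, 'pid'].tolist()[:5]}"
        )
    return pdf, jdf


def _violation_masks(pdf: pd.DataFrame, jdf: pd.DataFrame) -> dict[str, pd.Series]:
    """Boolean mask per exclusion criterion, indexed like ``pdf`` (un-ordered)."""
    by_pid = jdf.groupby("pid")
    has_jobs = pdf["pid"].isin(jdf["pid"])

    uncertain = pdf["pid"].map(by_pid["source_uncertain"].any()).astype("boolean").fillna(False).astype(bool)
    no_history = ~has_jobs

    year_unknown = jdf["start_year"].isna() | jdf["end_year"].isna()
    incoherent = (~year_unknown) & (jdf["end_year"] < jdf["start_year"])
    chron_bad = (year_unknown | incoherent).groupby(jdf["pid"]).any()
    chron = pdf["pid"].map(chron_bad).astype("boolean").fillna(False).astype(bool)

    all_nonstandard = pdf["pid"].map(by_pid["nonstandard"].all()).astype("boolean").fillna(False).astype(bool)
    all_nonstandard &= has_jobs

    code = jdf["isco88"].astype("string")
    unknown_code = (~jdf["nonstandard"]) & (code.isna() | (code == UNKNOWN_CODE))
    unknown = pdf["pid"].map(unknown_code.groupby(jdf["pid"]).any()).astype("boolean").fillna(False).astype(bool)

    return {
        "uncertain_source_or_no_history": uncertain | no_history,
        "missing_education": pdf["education"] == "missing",
        "chronology": chron,
        "nonstandard_only": all_nonstandard,
        "unknown_occupation": unknown,
    }


def apply_exclusions(
    pdf: pd.DataFrame, jdf: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLedger]:
    """Apply the study's ordered exclusion cascade.

    Criteria, in order: (1) uncertain/unknown RF-EMF source information or no
    occupational history; (2) missing education; (3) chronological issues
    (unknown years, end before start); (4) history consisting solely of
    nonstandard occupations; (5) any unknown occupation code.  A participant
    matching several criteria is counted only under the first.  Nonstandard
    spells held alongside real jobs are retained as unexposed periods.
    """
    masks = _violation_masks(pdf, jdf)
    statuses = [s for s in STATUSES if (pdf["status"] == s).any()] or list(STATUSES)
    initial = {s: int((pdf["status"] == s).sum()) for s in statuses}

    remaining = pd.Series(True, index=pdf.index)
    steps: list[tuple[str, dict[str, int]]] = []
    for label in EXCLUSION_CRITERIA:
        hit = masks[label] & remaining
        steps.append(
            (label, {s: int((hit & (pdf["status"] == s)).sum()) for s in statuses})
        )
        remaining &= ~hit

    included = pdf.loc[remaining].reset_index(drop=True)
    jobs_included = jdf[jdf["pid"].isin(included["pid"])].reset_index(drop=True)
    ledger = ExclusionLedger(
        initial=initial,
        steps=steps,
        final={s: int((included["status"] == s).sum()) for s in statuses},
    )
    ledger.validate()
    return included, jobs_included, ledger


def median_diagnosis_interview_gap(cases: pd.DataFrame) -> float:
    """Median of (interview year - diagnosis year) over cases with both years."""
    eligible = cases[
        cases["status"].isin(CASE_STATUSES)
        & cases["diagnosis_year"].notna()
        & cases["interview_year"].notna()
    ]
    if eligible.empty:
        raise DataError("no cases with both diagnosis and interview years")
    gaps = (eligible["interview_year"] - eligible["diagnosis_year"]).astype(float)
    return float(np.median(gaps))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reference_year(status: str, diagnosis_year, interview_year, median_gap: float) -> int:
    """Reference date (year resolution): diagnosis year for cases; interview
    year minus the cases' median diagnosis-interview gap for controls."""
    if median_gap < 0:
        raise DataError(f"median gap must be >= 0, got {median_gap}")
    if status in CASE_STATUSES:
        if pd.isna(diagnosis_year):
            raise DataError("case without diagnosis year")
        return int(diagnosis_year)
    return int(interview_year) - _round_half_up(median_gap)


def reference_years(pdf: pd.DataFrame, median_gap: float) -> pd.Series:
    """Vectorized :func:`reference_year`, indexed by pid."""
    years = [
        reference_year(row.status, row.diagnosis_year, row.interview_year, median_gap)
        for row in pdf.itertuples(index=False)
    ]
    return pd.Series(years, index=pdf["pid"].to_numpy(), name="reference_year")


def summarize_cohort(pdf: pd.DataFrame) -> pd.DataFrame:
    """Sociodemographic margins by status group (a "Table 1").

    Returns tidy rows (variable, level, status, n, pct) where pct is the
    within-group percentage of each level of each variable.
    """
    rows = []
    for variable in ("age_group", "sex", "region", "education"):
        for status, group in pdf.groupby("status"):
            total = len(group)
            for level, n in group[variable].value_counts().items():
                rows.append(
                    {
                        "variable": variable,
                        "level": level,
                        "status": status,
                        "n": int(n),
                        "pct": 100.0 * n / total,
                    }
                )
    return pd.DataFrame(rows, columns=["variable", "level", "status", "n", "pct"])
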