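"""Exposure metrics: job history x JEM -> yearly series -> cumulative / TWA.

Three increasingly restrictive linkage methods attribute matrix intensities
to job spells:

* ``M1`` — every job whose occupation code carries exposure in the matrix
  contributes its intensity.
* ``M2`` — as M1, but occupations whose exposure prevalence falls below the
  median prevalence among exposed occupations are treated as unexposed
  (fewer false positives at the cost of sensitivity).
* ``M3`` — only jobs in which the participant personally reported use of an
  RF-EMF source contribute.

A spell covers calendar years ``start..end`` inclusive; years covered by
several concurrent spells take the arithmetic mean of the concurrent spell
intensities (unexposed spells entering as zero).  Cumulative exposure under
lag L sums the series over years ``<= ref - L``; the window (a, b) sums over
``[ref - b, ref - a]``.  These conventions make the identity

    cumulative(lag 1) = window(1-4) + window(5-9) + cumulative(lag 10)

exact.  The time-weighted average divides cumulative exposure by the number
of years worked in the same span (0 when no years were worked).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractViolation, DataError
from .jem import Jem

METHODS = ("M1", "M2", "M3")

#: label -> ("lag", L) or ("window", a, b); all in years before the reference date.
LABELS: dict[str, tuple] = {
    "lag1": ("lag", 1),
    "lag5": ("lag", 5),
    "lag10": ("lag", 10),
    "lag15": ("lag", 15),
    "lag20": ("lag", 20),
    "lag25": ("lag", 25),
    "win1_4": ("window", 1, 4),
    "win5_9": ("window", 5, 9),
    "win10_14": ("window", 10, 14),
    "win15_19": ("window", 15, 19),
    "win20_24": ("window", 20, 24),
}

#: Labels of the main analysis; longer lags/windows probe longer latencies.
PRIMARY_LABELS = ("lag1", "lag5", "lag10", "win1_4", "win5_9")
EXTENDED_LABELS = ("lag15", "lag20", "lag25", "win10_14", "win15_19", "win20_24")

PROFILE_COLUMNS = [
    "pid", "field_kind", "method", "label",
    "cumulative", "twa", "years_worked", "exposed",
]


@dataclass
class YearlySeries:
    """Per-participant intensity by calendar year under one method and field."""

    pid: str
    field_kind: str
    method: str
    values: dict[int, float] = field(default_factory=dict)
    worked: dict[int, bool] = field(default_factory=dict)


def _spell_intensity(spell, jem: Jem, method: str, field_kind: str,
                     threshold: float | None) -> float:
    """Intensity a single spell contributes per year under a linkage method."""
    if spell.nonstandard:
        return 0.0
    code = spell.isco88
    if code is None or (isinstance(code, float) and pd.isna(code)):
        raise ContractViolation(f"spell for {spell.pid} has no occupation code")
    intensity = jem.intensity(str(code), field_kind)
    if method == "M2":
        if threshold is None:
            raise DataError("method M2 requires a prevalence threshold")
        if jem.prevalence(str(code), field_kind) < threshold:
            return 0.0
    elif method == "M3":
        if not spell.source_reported:
            return 0.0
    elif method != "M1":
        raise DataError(f"unknown method {method!r}")
    return intensity


def yearly_series(pid: str, spells, jem: Jem, method: str, field_kind: str,
                  threshold: float | None = None) -> YearlySeries:
    """Build the calendar-year intensity series for one participant.

    ``spells`` is an iterable of job-spell records (rows of the jobs table).
    Unknown years must have been excluded upstream; encountering one here is
    a contract violation.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for spell in spells:
        if pd.isna(spell.start_year) or pd.isna(spell.end_year):
            raise ContractViolation(f"spell for {pid} has unknown years")
        start, end = int(spell.start_year), int(spell.end_year)
        if end < start:
            raise ContractViolation(f"spell for {pid} ends before it starts")
        intensity = _spell_intensity(spell, jem, method, field_kind, threshold)
        for year in range(start, end + 1):
            sums[year] = sums.get(year, 0.0) + intensity
            counts[year] = counts.get(year, 0) + 1
    values = {y: sums[y] / counts[y] for y in sums}
    worked = {y: True for y in counts}
    return YearlySeries(pid=pid, field_kind=field_kind, method=method,
                        values=values, worked=worked)


def _label_bounds(label: str, ref_year: int) -> tuple[float, float]:
    kind = LABELS[label]
    if kind[0] == "lag":
        return (float("-inf"), ref_year - kind[1])
    _, a, b = kind
    return (ref_year - b, ref_year - a)


def cumulative_exposure(s: YearlySeries, ref_year: int, lag: int) -> float:
    """Sum of yearly intensity over years up to ``ref_year - lag``."""
    if lag < 1:
        raise DataError(f"lag must be >= 1, got {lag}")
    cut = ref_year - lag
    return float(sum(v for y, v in s.values.items() if y <= cut))


def window_exposure(s: YearlySeries, ref_year: int, a: int, b: int) -> float:
    """Sum of yearly intensity over the window ``[ref - b, ref - a]``."""
    if not (1 <= a <= b):
        raise DataError(f"window must satisfy 1 <= a <= b, got ({a}, {b})")
    lo, hi = ref_year - b, ref_year - a
    return float(sum(v for y, v in s.values.items() if lo <= y <= hi))


def years_worked(s: YearlySeries, ref_year: int, label: str) -> int:
    """Count of worked calendar years inside a label's year range."""
    lo, hi = _label_bounds(label, ref_year)
    return sum(1 for y, w in s.worked.items() if w and lo <= y <= hi)


def twa_exposure(cumulative: float, years: int) -> float:
    """Cumulative exposure divided by years worked; 0 when no years worked."""
    if years < 0:
        raise DataError("years worked cannot be negative")
    if years == 0:
        if cumulative > 0:
            raise ContractViolation("positive exposure with zero years worked")
        return 0.0
    return cumulative / years


@dataclass
class ExposureProfile:
    """Metric values for one participant x field x method across labels."""

    pid: str
    field_kind: str
    method: str
    cumulative: dict[str, float]
    twa: dict[str, float]
    years_worked: dict[str, int]
    exposed: dict[str, bool]


def compute_profile(s: YearlySeries, ref_year: int,
                    labels=PRIMARY_LABELS) -> ExposureProfile:
    cum: dict[str, float] = {}
    twa: dict[str, float] = {}
    years: dict[str, int] = {}
    exposed: dict[str, bool] = {}
    for label in labels:
        kind = LABELS[label]
        if kind[0] == "lag":
            value = cumulative_exposure(s, ref_year, kind[1])
        else:
            value = window_exposure(s, ref_year, kind[1], kind[2])
        n_years = years_worked(s, ref_year, label)
        cum[label] = value
        years[label] = n_years
        twa[label] = twa_exposure(value, n_years)
        exposed[label] = value > 0
    return ExposureProfile(pid=s.pid, field_kind=s.field_kind, method=s.method,
                           cumulative=cum, twa=twa, years_worked=years,
                           exposed=exposed)


def compute_profiles(
    pdf: pd.DataFrame,
    jdf: pd.DataFrame,
    jem: Jem,
    ref_years: pd.Series,
    methods=("M1",),
    fields=("E",),
    labels=PRIMARY_LABELS,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format exposure profiles for a whole cohort.

    ``ref_years`` maps pid -> reference year.  ``thresholds`` maps field
    kind -> Method-2 prevalence threshold (required only when "M2" is among
    the methods).  Returns one row per (pid, field, method, label).
    """
    from .jem import median_prevalence_threshold

    if "M2" in methods and thresholds is None:
        thresholds = {fk: median_prevalence_threshold(jem, fk) for fk in fields}
    spells_by_pid: dict[str, list] = {}
    for spell in jdf.itertuples(index=False):
        spells_by_pid.setdefault(spell.pid, []).append(spell)
    rows = []
    for pid in pdf["pid"]:
        spells = spells_by_pid.get(pid, [])
        ref = int(ref_years[pid])
        for fk in fields:
            for method in methods:
                thr = thresholds.get(fk) if (thresholds and method == "M2") else None
                s = yearly_series(pid, spells, jem, method, fk, thr)
                prof = compute_profile(s, ref, labels)
                for label in labels:
                    rows.append((pid, fk, method, label,
                                 prof.cumulative[label], prof.twa[label],
                                 prof.years_worked[label], prof.exposed[label]))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
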