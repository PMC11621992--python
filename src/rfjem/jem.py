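"""Job-exposure matrix (JEM) for occupational RF-EMF.

A JEM assigns, to each 4-digit ISCO88 occupation code and field kind
(electric E or magnetic H), a dimensionless exposure *intensity* — the
time-weighted-average ICNIRP squared ratio, proportional to the specific
absorption rate above 100 kHz — and a *prevalence*, the fraction of workers
in that occupation considered exposed.

Intensity for a single source measurement is ``(mean field / occupational
reference level)**2``; combining sources into one cell per occupation is
upstream of this package, but the squared-ratio primitive is exposed so a
synthetic matrix can be built from synthetic measurements.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .errors import (
    DuplicateKeyError,
    InvalidMeasurementError,
    SchemaError,
    UndefinedThresholdError,
)

FIELD_KINDS = ("E", "H")

#: Minimum frequency (Hz) at which the squared-ratio ~ SAR approximation holds.
MIN_FREQUENCY_HZ = 100e3

JEM_COLUMNS = ["isco88", "field_kind", "intensity", "prevalence", "n_basis"]


@dataclass(frozen=True)
class SourceMeasurement:
    """Mean E or H field level of one occupational source at one frequency.

    ``mean_field`` and ``reference_level`` share units (V/m for E, A/m for H);
    ``reference_level`` is the frequency-specific occupational reference level.
    """

    source_id: str
    frequency_hz: float
    field_kind: str
    mean_field: float
    reference_level: float

    def __post_init__(self) -> None:
        if self.field_kind not in FIELD_KINDS:
            raise InvalidMeasurementError(f"field_kind must be E or H, got {self.field_kind!r}")
        if self.frequency_hz <= MIN_FREQUENCY_HZ:
            raise InvalidMeasurementError(
                f"frequency {self.frequency_hz} Hz is outside the >100 kHz scope"
            )
        if self.mean_field < 0:
            raise InvalidMeasurementError("mean_field must be >= 0")
        if self.reference_level <= 0:
            raise InvalidMeasurementError("reference_level must be > 0")


def icnirp_squared_ratio(m: SourceMeasurement) -> float:
    """Squared ratio of mean field to its occupational reference level.

    Dimensionless; proportional to SAR for frequencies above 100 kHz.
    Scale-invariant: rescaling field and reference level together leaves
    the ratio unchanged.
    """
    return (m.mean_field / m.reference_level) ** 2


@dataclass(frozen=True)
class JemEntry:
    """One cell of the matrix: intensity and prevalence for (isco88, field)."""

    isco88: str
    field_kind: str
    intensity: float
    prevalence: float
    n_basis: int = 0

    def __post_init__(self) -> None:
        if self.field_kind not in FIELD_KINDS:
            raise SchemaError(f"field_kind must be E or H, got {self.field_kind!r}")
        if not (len(self.isco88) == 4 and self.isco88.isdigit()):
            raise SchemaError(f"isco88 must be a 4-digit code, got {self.isco88!r}")
        if self.intensity < 0:
            raise SchemaError(f"intensity must be >= 0, got {self.intensity}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise SchemaError(f"prevalence must be in [0, 1], got {self.prevalence}")

    @property
    def exposed(self) -> bool:
        return self.prevalence > 0


class Jem:
    """Collection of :class:`JemEntry`, unique per (isco88, field_kind).

    Lookup of an absent code yields "unexposed" (intensity 0), never an
    error: occupations missing from the matrix carry no exposure.  An entry
    with prevalence 0 likewise contributes intensity 0 downstream.
    """

    def __init__(self, entries: Iterable[JemEntry] = ()) -> None:
        self._entries: dict[tuple[str, str], JemEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: JemEntry) -> None:
        key = (entry.isco88, entry.field_kind)
        if key in self._entries:
            raise DuplicateKeyError(f"duplicate JEM entry for {key}")
        self._entries[key] = entry

    def get(self, isco88: str, field_kind: str) -> JemEntry | None:
        return self._entries.get((isco88, field_kind))

    def intensity(self, isco88: str, field_kind: str) -> float:
        """Intensity assigned to a code; 0 if absent or prevalence is 0."""
        e = self._entries.get((isco88, field_kind))
        if e is None or e.prevalence == 0:
            return 0.0
        return e.intensity

    def prevalence(self, isco88: str, field_kind: str) -> float:
        e = self._entries.get((isco88, field_kind))
        return 0.0 if e is None else e.prevalence

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[JemEntry]:
        return iter(self._entries.values())

    def codes(self, field_kind: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for (code, fk) in self._entries:
            if field_kind is None or fk == field_kind:
                seen.setdefault(code)
        return list(seen)


def median_prevalence_threshold(jem: Jem, field_kind: str) -> float:
    """Median prevalence among *exposed* entries (prevalence > 0) of a field.

    This is the gate used by the prevalence-restricted linkage method
    (Method 2): occupations below the threshold are treated as unexposed.
    Even-count median is the mean of the two middle values.
    """
    prevs = [e.prevalence for e in jem if e.field_kind == field_kind and e.prevalence > 0]
    if not prevs:
        raise UndefinedThresholdError(
            f"no exposed entries for field {field_kind!r}; median prevalence undefined"
        )
    return float(statistics.median(prevs))


def load_jem(path) -> Jem:
    """Read a matrix from CSV (columns ``isco88,field_kind,intensity,prevalence,n_basis``).

    Rows violating entry invariants are rejected with row-numbered messages;
    an empty file with a header yields an empty, usable matrix.
    """
    df = pd.read_csv(path, dtype={"isco88": str})
    missing = [c for c in JEM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"JEM file {path} missing columns: {missing}")
    jem = Jem()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            entry = JemEntry(
                isco88=str(row.isco88).zfill(4),
                field_kind=str(row.field_kind),
                intensity=float(row.intensity),
                prevalence=float(row.prevalence),
                n_basis=int(row.n_basis),
            )
            jem.add(entry)
        except DuplicateKeyError as err:
            raise DuplicateKeyError(f"{path} line {i}: {err}") from None
        except (SchemaError, ValueError) as err:
            raise SchemaError(f"{path} line {i}: {err}") from None
    return jem


def write_jem(jem: Jem, path) -> None:
    """Write a matrix to CSV; inverse of :func:`load_jem` on valid input."""
    df = pd.DataFrame(
        [
            {
                "isco88": e.isco88,
                "field_kind": e.field_kind,
                "intensity": e.intensity,
                "prevalence": e.prevalence,
                "n_basis": e.n_basis,
            }
            for e in jem
        ],
        columns=JEM_COLUMNS,
    )
    df.to_csv(path, index=False)
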