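"""Core record types shared across the pipeline.

These mirror the linked tables of a genealogy-medical registry: a person
table with stratum attributes, diagnosis/procedure events with ICD codes,
laboratory results, and cancer registry records with SEER site codes.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class CodeSystem(str, enum.Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


@dataclass(frozen=True)
class Person:
    """Demographic unit carrying stratum attributes.

    birthplace is the binary registry class (``UTAH`` / ``NON_UTAH``); an
    unknown birthplace is stored as None and resolved downstream.
    """

    person_id: str
    sex: str  # "M" or "F"
    birth_year: int
    birthplace: str | None = None
    birth_date: dt.date | None = None
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"person {self.person_id}: sex must be M or F, got {self.sex!r}")


@dataclass(frozen=True)
class DiagnosisEvent:
    person_id: str
    code: str
    code_system: str  # "ICD9" or "ICD10"
    date: dt.date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code must be non-empty")
        if self.code_system not in ("ICD9", "ICD10"):
            raise ValueError(f"unknown code system {self.code_system!r}")


@dataclass(frozen=True)
class LabResult:
    """FSH (IU/L) or AMH (ng/mL) result with draw date."""

    person_id: str
    analyte: str  # "FSH" or "AMH"
    value: float
    date: dt.date

    def __post_init__(self) -> None:
        if self.analyte not in ("FSH", "AMH"):
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.value < 0:
            raise ValueError("lab value must be non-negative")


class ProcedureKind(str, enum.Enum):
    """Exclusion-relevant procedures/treatments."""

    HYSTERECTOMY = "HYSTERECTOMY"
    OOPHORECTOMY = "OOPHORECTOMY"
    ENDOMETRIOSIS_PELVIC_SURGERY = "ENDOMETRIOSIS_PELVIC_SURGERY"
    PELVIC_RADIATION = "PELVIC_RADIATION"
    CHEMOTHERAPY = "CHEMOTHERAPY"


@dataclass(frozen=True)
class ProcedureEvent:
    person_id: str
    procedure: str  # ProcedureKind value
    date: dt.date

    def __post_init__(self) -> None:
        ProcedureKind(self.procedure)  # raises on unknown kind


@dataclass(frozen=True)
class CancerRecord:
    """One registry cancer diagnosis, coded by SEER site recode."""

    person_id: str
    seer_code: int
    date: dt.date


def age_at(birth_year: int, date: dt.date) -> int:
    """Completed years at an event date, from birth year only.

    Registry extracts often carry birth year but not full birth dates, so
    age is floored to event_year - birth_year.
    """
    return date.year - birth_year


@dataclass
class TableBundle:
    """Convenience bundle of per-person record lists, keyed for O(1) lookup."""

    events: dict[str, list[DiagnosisEvent]] = field(default_factory=dict)
    labs: dict[str, list[LabResult]] = field(default_factory=dict)
    procedures: dict[str, list[ProcedureEvent]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        events: list[DiagnosisEvent] = (),
        labs: list[LabResult] = (),
        procedures: list[ProcedureEvent] = (),
    ) -> "TableBundle":
        b = cls()
        for e in events:
            b.events.setdefault(e.person_id, []).append(e)
        for l in labs:
            b.labs.setdefault(l.person_id, []).append(l)
        for p in procedures:
            b.procedures.setdefault(p.person_id, []).append(p)
        return b
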