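"""EMR-style case ascertainment for POI and early menopause.

A woman is classified as a POI case from the earliest qualifying evidence:

* a POI diagnosis code — ICD-9 256.3/256.31/256.39 or ICD-10
  E28.3/E28.31/E28.39/E28.310/E28.319 — recorded at or before age 40, or
* a qualifying laboratory result — FSH strictly above 20 IU/L or AMH
  strictly below 0.08 ng/mL — drawn before age 40.

Early-menopause mode applies the same criteria in the age window
40 < age < 45. Cases are excluded when hysterectomy, oophorectomy,
endometriosis with pelvic surgery, pelvic radiation or chemotherapy
precedes the index date, or when a Turner-syndrome code (ICD-9 758.6,
ICD-10 Q96.*) appears at any date — Turner syndrome is congenital, so the
temporal qualifier applying to acquired exclusions does not apply to it.

Lab thresholds are strict inequalities; FSH exactly 20 IU/L does not
qualify. Ages are completed years computed from birth year.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import DiagnosisEvent, LabResult, Person, ProcedureEvent, age_at

POI_CODES = {
    "ICD9": ("256.3", "256.31", "256.39"),
    "ICD10": ("E28.3", "E28.31", "E28.39", "E28.310", "E28.319"),
}
TURNER_CODES = {
    "ICD9": ("758.6",),
    "ICD10": ("Q96",),
}

FSH_THRESHOLD_IU_L = 20.0
AMH_THRESHOLD_NG_ML = 0.08

POI_MAX_AGE = 40  # inclusive: POI is diagnosed at age <= 40
EARLY_MENOPAUSE_WINDOW = (40, 45)  # exclusive on both sides: 40 < age < 45


class Classification(str, enum.Enum):
    POI = "POI"
    EARLY_MENOPAUSE = "EARLY_MENOPAUSE"
    NOT_CASE = "NOT_CASE"
    EXCLUDED = "EXCLUDED"


class ExclusionReason(str, enum.Enum):
    HYSTERECTOMY = "HYSTERECTOMY"
    OOPHORECTOMY = "OOPHORECTOMY"
    ENDOMETRIOSIS_PELVIC_SURGERY = "ENDOMETRIOSIS_PELVIC_SURGERY"
    PELVIC_RADIATION = "PELVIC_RADIATION"
    CHEMOTHERAPY = "CHEMOTHERAPY"
    TURNER = "TURNER"


@dataclass
class CaseStatus:
    person_id: str
    classification: Classification
    index_date: dt.date | None = None
    evidence: list[tuple[str, str]] = field(default_factory=list)
    exclusion_reason: ExclusionReason | None = None


def match_code(code: str, system: str, patterns: Sequence[str]) -> bool:
    """Dot-aware prefix match of an ICD code against a pattern list.

    True iff the code equals a pattern or extends it at a subcode boundary:
    E28.31 and E28.310 match E28.3, and a pattern without a dot (Q96)
    matches any of its dotted subcodes (Q96.1). Codes that merely share
    leading characters (E28.8 against E28.3) do not match.
    """
    if system not in ("ICD9", "ICD10"):
        raise ValueError(f"unknown code system {system!r}")
    code = code.strip().upper()
    for pat in patterns:
        pat = pat.strip().upper()
        if code == pat:
            return True
        # extension at a subcode boundary: either the pattern already ends at
        # a dot-group ("E28.3" -> "E28.31"), or the code adds ".x" ("Q96" -> "Q96.1")
        if code.startswith(pat) and (pat.endswith(".") or "." in pat or code[len(pat)] == "."):
            return True
    return False


def _qualifying_lab(lab: LabResult) -> bool:
    if lab.analyte == "FSH":
        return lab.value > FSH_THRESHOLD_IU_L
    return lab.value < AMH_THRESHOLD_NG_ML


def _in_window(age: int, mode: Classification) -> bool:
    if mode == Classification.POI:
        return age <= POI_MAX_AGE
    lo, hi = EARLY_MENOPAUSE_WINDOW
    return lo < age < hi


def ascertain(
    person: Person,
    events: Iterable[DiagnosisEvent],
    labs: Iterable[LabResult],
    mode: Classification = Classification.POI,
) -> CaseStatus:
    """Classify one woman from her coded events and laboratory results.

    The index date is the earliest qualifying record (code or lab) inside
    the mode's age window; with no qualifying evidence the result is
    NOT_CASE. Record order does not matter.
    """
    if mode not in (Classification.POI, Classification.EARLY_MENOPAUSE):
        raise ValueError(f"mode must be POI or EARLY_MENOPAUSE, got {mode}")
    if person.sex != "F":
        raise ValueError(f"person {person.person_id}: ascertainment applies to women only")
    if person.birth_year is None:
        raise ValueError(f"person {person.person_id}: birth year required")

    hits: list[tuple[dt.date, str, str]] = []
    for e in events:
        if e.person_id != person.person_id:
            continue
        if match_code(e.code, e.code_system, POI_CODES[e.code_system]) and _in_window(
            age_at(person.birth_year, e.date), mode
        ):
            hits.append((e.date, "icd_code", f"{e.code_system}:{e.code}"))
    for l in labs:
        if l.person_id != person.person_id:
            continue
        if _qualifying_lab(l) and _in_window(age_at(person.birth_year, l.date), mode):
            hits.append((l.date, "lab", f"{l.analyte}={l.value:g}"))

    if not hits:
        return CaseStatus(person.person_id, Classification.NOT_CASE)
    hits.sort()
    return CaseStatus(
        person_id=person.person_id,
        classification=mode,
        index_date=hits[0][0],
        evidence=[(kind, ref) for _, kind, ref in hits],
    )


def apply_exclusions(
    status: CaseStatus,
    events: Iterable[DiagnosisEvent],
    procedures: Iterable[ProcedureEvent],
) -> CaseStatus:
    """Apply exclusion filters to an ascertained case.

    Surgical/treatment exclusions must predate the index date; a Turner
    code excludes regardless of date. Non-cases pass through unchanged.
    """
    if status.classification not in (Classification.POI, Classification.EARLY_MENOPAUSE):
        return status

    for e in events:
        if e.person_id != status.person_id:
            continue
        if match_code(e.code, e.code_system, TURNER_CODES[e.code_system]):
            return CaseStatus(
                person_id=status.person_id,
                classification=Classification.EXCLUDED,
                index_date=status.index_date,
                evidence=status.evidence,
                exclusion_reason=ExclusionReason.TURNER,
            )

    dated: list[tuple[dt.date, ExclusionReason]] = [
        (p.date, ExclusionReason(p.procedure))
        for p in procedures
        if p.person_id == status.person_id and p.date < status.index_date
    ]
    if dated:
        dated.sort()
        return CaseStatus(
            person_id=status.person_id,
            classification=Classification.EXCLUDED,
            index_date=status.index_date,
            evidence=status.evidence,
            exclusion_reason=dated[0][1],
        )
    return status


def ascertain_cohort(
    persons: Sequence[Person],
    events: Sequence[DiagnosisEvent],
    labs: Sequence[LabResult],
    procedures: Sequence[ProcedureEvent] = (),
    mode: Classification = Classification.POI,
    chart_review: dict[str, bool] | None = None,
) -> list[CaseStatus]:
    """Ascertain every woman in the cohort and apply exclusions.

    Men and women without qualifying evidence yield NOT_CASE rows, so the
    output covers the full cohort and downstream attrition is auditable.
    ``chart_review`` optionally carries human adjudication: a False entry
    demotes an ascertained case to NOT_CASE (adjudication itself is not
    modeled, only its verdict).
    """
    by_person_events: dict[str, list[DiagnosisEvent]] = {}
    for e in events:
        by_person_events.setdefault(e.person_id, []).append(e)
    by_person_labs: dict[str, list[LabResult]] = {}
    for l in labs:
        by_person_labs.setdefault(l.person_id, []).append(l)
    by_person_procs: dict[str, list[ProcedureEvent]] = {}
    for p in procedures:
        by_person_procs.setdefault(p.person_id, []).append(p)

    out: list[CaseStatus] = []
    for person in persons:
        if person.sex != "F":
            out.append(CaseStatus(person.person_id, Classification.NOT_CASE))
            continue
        status = ascertain(
            person,
            by_person_events.get(person.person_id, ()),
            by_person_labs.get(person.person_id, ()),
            mode,
        )
        status = apply_exclusions(
            status,
            by_person_events.get(person.person_id, ()),
            by_person_procs.get(person.person_id, ()),
        )
        if (
            chart_review is not None
            and status.classification is mode
            and chart_review.get(person.person_id) is False
        ):
            status = CaseStatus(
                person_id=person.person_id,
                classification=Classification.NOT_CASE,
                evidence=status.evidence + [("chart_review", "rejected")],
            )
        out.append(status)
    return out
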