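"""Tab-separated table readers and writers.

All tables are TSV with a header row; dates are ISO-8601; missing values are
empty fields. Pedigrees travel in 6-column PED format (family, individual,
father, mother, sex 1=male/2=female, phenotype) with "0" for unknown parents.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable

import pandas as pd

from .records import CancerRecord, DiagnosisEvent, LabResult, Person, ProcedureEvent

PERSON_COLS = ["person_id", "sex", "birth_year", "birthplace", "birth_date", "death_date"]
EVENT_COLS = ["person_id", "code", "code_system", "date"]
LAB_COLS = ["person_id", "analyte", "value", "date"]
PROCEDURE_COLS = ["person_id", "procedure", "date"]
CANCER_COLS = ["person_id", "seer_code", "date"]


def _parse_date(v) -> dt.date | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return dt.date.fromisoformat(str(v))


def _fmt(v) -> str:
    return "" if v is None else str(v)


def _read(path: str | Path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_persons(path: str | Path) -> list[Person]:
    df = _read(path, PERSON_COLS)
    return [
        Person(
            person_id=r.person_id,
            sex=r.sex,
            birth_year=int(r.birth_year),
            birthplace=r.birthplace or None,
            birth_date=_parse_date(r.birth_date),
            death_date=_parse_date(r.death_date),
        )
        for r in df.itertuples()
    ]


def write_persons(persons: Iterable[Person], path: str | Path) -> int:
    rows = [
        [p.person_id, p.sex, p.birth_year, _fmt(p.birthplace), _fmt(p.birth_date), _fmt(p.death_date)]
        for p in persons
    ]
    pd.DataFrame(rows, columns=PERSON_COLS).to_csv(path, sep="\t", index=False)
    return len(rows)


def read_events(path: str | Path) -> list[DiagnosisEvent]:
    df = _read(path, EVENT_COLS)
    return [
        DiagnosisEvent(r.person_id, r.code, r.code_system, _parse_date(r.date))
        for r in df.itertuples()
    ]


def write_events(events: Iterable[DiagnosisEvent], path: str | Path) -> int:
    rows = [[e.person_id, e.code, e.code_system, e.date.isoformat()] for e in events]
    pd.DataFrame(rows, columns=EVENT_COLS).to_csv(path, sep="\t", index=False)
    return len(rows)


def read_labs(path: str | Path) -> list[LabResult]:
    df = _read(path, LAB_COLS)
    return [
        LabResult(r.person_id, r.analyte, float(r.value), _parse_date(r.date))
        for r in df.itertuples()
    ]


def write_labs(labs: Iterable[LabResult], path: str | Path) -> int:
    rows = [[l.person_id, l.analyte, repr(l.value), l.date.isoformat()] for l in labs]
    pd.DataFrame(rows, columns=LAB_COLS).to_csv(path, sep="\t", index=False)
    return len(rows)


def read_procedures(path: str | Path) -> list[ProcedureEvent]:
    df = _read(path, PROCEDURE_COLS)
    return [ProcedureEvent(r.person_id, r.procedure, _parse_date(r.date)) for r in df.itertuples()]


def write_procedures(procs: Iterable[ProcedureEvent], path: str | Path) -> int:
    rows = [[p.person_id, p.procedure, p.date.isoformat()] for p in procs]
    pd.DataFrame(rows, columns=PROCEDURE_COLS).to_csv(path, sep="\t", index=False)
    return len(rows)


def read_cancers(path: str | Path) -> list[CancerRecord]:
    df = _read(path, CANCER_COLS)
    return [
        CancerRecord(r.person_id, int(r.seer_code), _parse_date(r.date)) for r in df.itertuples()
    ]


def write_cancers(cancers: Iterable[CancerRecord], path: str | Path) -> int:
    rows = [[c.person_id, c.seer_code, c.date.isoformat()] for c in cancers]
    pd.DataFrame(rows, columns=CANCER_COLS).to_csv(path, sep="\t", index=False)
    return len(rows)


def write_ped(
    trios: Iterable[tuple[str, str, str]],
    sex: dict[str, str],
    path: str | Path,
    family_of: dict[str, str] | None = None,
    extra_ids: Iterable[str] = (),
) -> int:
    """Write 6-column PED lines: one per individual, trio rows for children.

    ``trios`` are (child, father, mother) with "0" for an unknown parent.
    Individuals appearing only as parents (or in ``extra_ids``) get
    founder rows with both parents "0".
    """
    trios = list(trios)
    parents_of = {c: (f, m) for c, f, m in trios}
    ids: list[str] = []
    seen = set()
    for c, f, m in trios:
        for i in (c, f, m):
            if i != "0" and i not in seen:
                seen.add(i)
                ids.append(i)
    for i in extra_ids:
        if i not in seen:
            seen.add(i)
            ids.append(i)
    sex_code = {"M": "1", "F": "2"}
    with open(path, "w") as fh:
        for i in sorted(ids):
            f, m = parents_of.get(i, ("0", "0"))
            fam = family_of.get(i, "FAM1") if family_of else "FAM1"
            fh.write(f"{fam}\t{i}\t{f}\t{m}\t{sex_code.get(sex.get(i, 'U'), '0')}\t0\n")
    return len(ids)
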