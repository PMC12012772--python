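"""Synthetic genealogy-medical registry generator.

Emulates the linked data model of a population genealogy database joined to
an EMR and a state cancer registry: a multi-generation pedigree of
monogamous, non-consanguineous founder couples whose descendants marry
unrelated spawned spouses, a person table with sex, birth year and binary
birthplace class, diagnosis/lab evidence for planted POI carriers, and
lifetime cancer outcomes drawn per person as a single Bernoulli trial.

Cancer probability for a person is the baseline rate of their stratum
times a planted familial multiplier: persons standing in a first-, second-
or third-degree relationship to a POI carrier (or carriers themselves,
"degree 0") take the largest multiplier applicable to any of their
relationships. This lets downstream relative-risk estimation be checked
against known truth: with all multipliers 1 the pipeline should see RR = 1,
and a planted multiplier should be recovered within its confidence bounds.

All randomness flows through one seeded generator; a config without a seed
is rejected so every dataset is reproducible.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as fio
from .pedigree import PedigreeGraph, RelationType, _relatives_by_degree
from .records import CancerRecord, DiagnosisEvent, LabResult, Person, ProcedureEvent
from .sites import ALL_SITES, CANONICAL_CODE, SITE_SEX
from .risk import Stratum, assign_stratum

#: default lifetime cumulative rates per site, order-of-magnitude realistic
#: for a US registry population (breast/prostate most common, testis rare).
DEFAULT_BASELINE_RATES: dict[str, float] = {
    "breast": 0.12,
    "ovary": 0.012,
    "uterus": 0.03,
    "colon": 0.04,
    "prostate": 0.12,
    "testis": 0.004,
}


class SimConfig(BaseModel):
    """Parameters of one synthetic registry draw.

    ``baseline_rates`` maps each site to either a scalar rate (applied in
    every stratum) or a mapping from stratum patterns to rates; patterns are
    "SEX|COHORT|PLACE", "SEX|PLACE", "SEX", "PLACE" or "*", resolved
    most-specific first. ``familial_rr`` maps "site:degree" (degree 0 =
    the POI carrier herself) to a risk multiplier.
    """

    n_founder_couples: int = Field(default=80, ge=1)
    n_generations: int = Field(default=4, ge=3)
    birth_year_range: tuple[int, int] = (1920, 1935)
    p_utah_birth: float = Field(default=0.75, ge=0.0, le=1.0)
    baseline_rates: dict[str, float | dict[str, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES)
    )
    poi_prevalence: float = Field(default=0.011, ge=0.0, le=1.0)
    familial_rr: dict[str, float] = Field(default_factory=dict)
    mean_children: float = Field(default=2.6, gt=0.0)
    p_second_union: float = Field(default=0.0, ge=0.0, le=1.0)
    generation_gap_years: tuple[int, int] = (20, 35)
    seed: int

    @field_validator("birth_year_range")
    @classmethod
    def _year_range(cls, v):
        if v[0] > v[1]:
            raise ValueError("birth_year_range: start year exceeds end year")
        return v

    @field_validator("baseline_rates")
    @classmethod
    def _rates(cls, v):
        for site, spec in v.items():
            if site not in ALL_SITES:
                raise ValueError(f"baseline_rates: unknown site {site!r}")
            vals = spec.values() if isinstance(spec, dict) else [spec]
            for r in vals:
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"baseline_rates[{site}]: rate {r} outside [0, 1]")
        return v

    @field_validator("familial_rr")
    @classmethod
    def _rr(cls, v):
        for key, mult in v.items():
            site, _, deg = key.partition(":")
            if site not in ALL_SITES or deg not in ("0", "1", "2", "3"):
                raise ValueError(f"familial_rr: key {key!r} is not 'site:degree'")
            if not np.isfinite(mult) or mult < 0:
                raise ValueError(f"familial_rr[{key}]: multiplier must be finite and >= 0")
        return v


def resolve_rate(spec: float | Mapping[str, float], stratum: Stratum) -> float:
    """Resolve a baseline-rate spec for one stratum, most-specific first."""
    if not isinstance(spec, Mapping):
        return float(spec)
    for key in (
        f"{stratum.sex}|{stratum.cohort_start}|{stratum.birthplace}",
        f"{stratum.sex}|{stratum.birthplace}",
        stratum.sex,
        stratum.birthplace,
        "*",
    ):
        if key in spec:
            return float(spec[key])
    raise KeyError(f"no baseline rate for stratum {stratum}")


@dataclass
class RegistryDataset:
    """Linked synthetic tables plus the planted ground truth."""

    persons: list[Person] = field(default_factory=list)
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    events: list[DiagnosisEvent] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    procedures: list[ProcedureEvent] = field(default_factory=list)
    cancers: list[CancerRecord] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def person_index(self) -> dict[str, Person]:
        return {p.person_id: p for p in self.persons}

    def graph(self) -> PedigreeGraph:
        g = PedigreeGraph()
        for p in self.persons:
            g.add_individual(p.person_id, p.sex)
        for child, father, mother in self.trios:
            g.set_parents(child, father or None, mother or None)
        g.validate()
        return g


def _date(rng: np.random.Generator, year: int) -> dt.date:
    day = int(rng.integers(1, 29))
    month = int(rng.integers(1, 13))
    return dt.date(year, month, day)


def simulate_population(config: SimConfig) -> RegistryDataset:
    """Draw one synthetic registry according to ``config``.

    Pedigree depth equals ``n_generations`` (founders are generation 0).
    POI is assigned to women only, with onset at age 18-40; every carrier
    receives both a qualifying diagnosis code and an elevated FSH at onset,
    so ascertainment sensitivity is 1 on clean data. Identical configs with
    identical seeds produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    ds = RegistryDataset()
    counter = 0

    def new_person(sex: str, birth_year: int) -> Person:
        nonlocal counter
        counter += 1
        birthplace = "UTAH" if rng.random() < config.p_utah_birth else "NON_UTAH"
        p = Person(
            person_id=f"P{counter:06d}",
            sex=sex,
            birth_year=birth_year,
            birthplace=birthplace,
            birth_date=_date(rng, birth_year),
        )
        ds.persons.append(p)
        return p

    # -- pedigree growth ---------------------------------------------------
    y0, y1 = config.birth_year_range
    gap_lo, gap_hi = config.generation_gap_years
    couples: list[tuple[Person, Person]] = []
    for _ in range(config.n_founder_couples):
        by = int(rng.integers(y0, y1 + 1))
        husband = new_person("M", by + int(rng.integers(-3, 4)))
        wife = new_person("F", by + int(rng.integers(-3, 4)))
        couples.append((husband, wife))

    generation = {p.person_id: 0 for p in ds.persons}
    for gen in range(1, config.n_generations):
        next_couples: list[tuple[Person, Person]] = []
        for husband, wife in couples:
            unions = [(husband, wife)]
            if config.p_second_union > 0 and rng.random() < config.p_second_union:
                other = new_person("F", wife.birth_year + int(rng.integers(-5, 6)))
                generation[other.person_id] = gen - 1
                unions.append((husband, other))
            for fa, mo in unions:
                n_kids = int(rng.poisson(config.mean_children))
                base = max(fa.birth_year, mo.birth_year)
                for _ in range(n_kids):
                    by = base + int(rng.integers(gap_lo, gap_hi + 1))
                    child = new_person("M" if rng.random() < 0.5 else "F", by)
                    generation[child.person_id] = gen
                    ds.trios.append((child.person_id, fa.person_id, mo.person_id))
                    if gen < config.n_generations - 1:
                        spouse = new_person(
                            "F" if child.sex == "M" else "M",
                            by + int(rng.integers(-5, 6)),
                        )
                        generation[spouse.person_id] = gen
                        # marry-ins carry their own recorded parents, as in a
                        # genealogy database; otherwise no descendant would
                        # ever have all four grandparents on record
                        sp_fa = new_person("M", spouse.birth_year - int(rng.integers(gap_lo, gap_hi + 1)))
                        sp_mo = new_person("F", spouse.birth_year - int(rng.integers(gap_lo, gap_hi + 1)))
                        generation[sp_fa.person_id] = gen - 1
                        generation[sp_mo.person_id] = gen - 1
                        ds.trios.append((spouse.person_id, sp_fa.person_id, sp_mo.person_id))
                        pair = (child, spouse) if child.sex == "M" else (spouse, child)
                        next_couples.append(pair)
        couples = next_couples

    graph = ds.graph()

    # -- POI assignment ----------------------------------------------------
    carriers: list[str] = []
    for p in ds.persons:
        if p.sex != "F":
            continue
        if rng.random() < config.poi_prevalence:
            carriers.append(p.person_id)
            onset_age = int(rng.integers(18, 41))
            onset = _date(rng, p.birth_year + onset_age)
            ds.events.append(DiagnosisEvent(p.person_id, "E28.319", "ICD10", onset))
            fsh = float(np.round(rng.uniform(25.0, 120.0), 1))
            ds.labs.append(LabResult(p.person_id, "FSH", fsh, onset))

    # -- familial multipliers ---------------------------------------------
    # degree of each person to the nearest carrier(s); carriers are degree 0
    degrees: dict[str, set[int]] = {c: {0} for c in carriers}
    for c in carriers:
        for deg, rels in _relatives_by_degree(graph, c).items():
            for pid in rels:
                degrees.setdefault(pid, set()).add(deg)

    rr = {tuple(k.split(":")): v for k, v in config.familial_rr.items()}

    def multiplier(pid: str, site: str) -> float:
        degs = degrees.get(pid)
        if not degs:
            return 1.0
        # a person related to several carriers takes the largest applicable
        # multiplier; effects never compound
        return max((rr.get((site, str(d)), 1.0) for d in degs), default=1.0)

    # -- cancer outcomes ---------------------------------------------------
    for p in ds.persons:
        stratum = assign_stratum(p)
        for site in ALL_SITES:
            if p.sex not in SITE_SEX[site]:
                continue
            spec = config.baseline_rates.get(site, 0.0)
            prob = min(resolve_rate(spec, stratum) * multiplier(p.person_id, site), 1.0)
            if prob > 0 and rng.random() < prob:
                dx_age = int(rng.integers(40, 81))
                ds.cancers.append(
                    CancerRecord(p.person_id, CANONICAL_CODE[site], _date(rng, p.birth_year + dx_age))
                )

    ds.truth = {
        "poi_carriers": carriers,
        "familial_rr": dict(config.familial_rr),
        "degree_to_carrier": {pid: min(d) for pid, d in degrees.items()},
        "generation": generation,
        "seed": config.seed,
    }
    return ds


# -- fixture round-trip ----------------------------------------------------

FIXTURE_FILES = (
    "persons.tsv",
    "pedigree.ped",
    "events.tsv",
    "labs.tsv",
    "procedures.tsv",
    "cancers.tsv",
)


def write_fixture(dataset: RegistryDataset, directory: str | Path) -> dict:
    """Write the dataset as TSV/PED files plus a row-count manifest.

    The written files round-trip losslessly through :func:`read_fixture`
    (persons, trios, events, labs, procedures, cancers).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sex = {p.person_id: p.sex for p in dataset.persons}
    manifest = {
        "persons": fio.write_persons(dataset.persons, directory / "persons.tsv"),
        "trios": len(dataset.trios),
        "events": fio.write_events(dataset.events, directory / "events.tsv"),
        "labs": fio.write_labs(dataset.labs, directory / "labs.tsv"),
        "procedures": fio.write_procedures(dataset.procedures, directory / "procedures.tsv"),
        "cancers": fio.write_cancers(dataset.cancers, directory / "cancers.tsv"),
    }
    fio.write_ped(
        dataset.trios,
        sex,
        directory / "pedigree.ped",
        extra_ids=[p.person_id for p in dataset.persons],
    )
    if dataset.truth:
        (directory / "truth.json").write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixture(directory: str | Path) -> RegistryDataset:
    """Read back a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    missing = [f for f in FIXTURE_FILES if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(f"fixture directory {directory} is missing {missing}")
    from .pedigree import parse_ped

    graph = parse_ped(directory / "pedigree.ped")
    trios = sorted(
        (c, graph.father.get(c, "0"), graph.mother.get(c, "0"))
        for c in set(graph.father) | set(graph.mother)
    )
    truth_path = directory / "truth.json"
    return RegistryDataset(
        persons=fio.read_persons(directory / "persons.tsv"),
        trios=trios,
        events=fio.read_events(directory / "events.tsv"),
        labs=fio.read_labs(directory / "labs.tsv"),
        procedures=fio.read_procedures(directory / "procedures.tsv"),
        cancers=fio.read_cancers(directory / "cancers.tsv"),
        truth=json.loads(truth_path.read_text()) if truth_path.exists() else {},
    )
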