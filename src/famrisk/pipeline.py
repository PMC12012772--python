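"""End-to-end orchestration: ascertain → eligibility → relatives → risk → pedigrees.

Every stage logs its attrition counts into the run manifest so the case
funnel (women screened, cases ascertained, excluded, genealogy-eligible)
is auditable, and any stage failure is re-raised tagged with the stage
name. Identical configs and seeds produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .ascertain import CaseStatus, Classification, ascertain_cohort
from .pedigree import PedigreeGraph, has_three_generation_genealogy, parse_ped, relative_sets
from .pedigree_excess import detect_high_risk, results_to_rows
from .records import Person
from .risk import (
    RiskEstimate,
    build_rate_table,
    estimate_risk,
    estimates_to_rows,
    expected_count,
    observed_count,
)
from .simulate import RegistryDataset, SimConfig, read_fixture, simulate_population, write_fixture
from .sites import ALL_SITES, SITE_SEX, bonferroni_tests

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class PipelineConfig(BaseModel):
    """One pipeline run: either simulate a registry or read one from disk."""

    simulate: SimConfig | None = None
    input_dir: str | None = None
    sites: list[str] = Field(default_factory=lambda: list(ALL_SITES))
    degrees: list[int] = Field(default_factory=lambda: [1, 2, 3])
    mode: str = "POI"
    alpha: float = Field(default=0.05, gt=0.0, le=1.0)
    n_tests_female: int = Field(default=4, ge=1)
    n_tests_male: int = Field(default=3, ge=1)
    pedigree_alpha: float = Field(default=0.05, gt=0.0, le=1.0)
    ancestors_only: bool = False
    mask: bool = False
    output_dir: str = "famrisk_out"

    def model_post_init(self, __context) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config must set either 'simulate' or 'input_dir'")


@dataclass
class PipelineResult:
    dataset: RegistryDataset
    graph: PedigreeGraph
    cases: list[CaseStatus]
    probands: list[str]
    estimates: list[RiskEstimate]
    pedigree_results: list
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("load")
def _load(config: PipelineConfig) -> RegistryDataset:
    if config.simulate is not None:
        return simulate_population(config.simulate)
    d = Path(config.input_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"input directory {d} does not exist")
    # missing inputs abort with the stage that needs them
    stage_of_file = {
        "persons.tsv": "load",
        "pedigree.ped": "pedigree",
        "events.tsv": "ascertain",
        "labs.tsv": "ascertain",
        "procedures.tsv": "ascertain",
        "cancers.tsv": "risk",
    }
    for fname, stage in stage_of_file.items():
        if not (d / fname).exists():
            raise StageError(stage, f"required input {d / fname} is missing")
    return read_fixture(d)


@_stage("pedigree")
def _graph(dataset: RegistryDataset) -> PedigreeGraph:
    return dataset.graph()


@_stage("ascertain")
def _ascertain(dataset: RegistryDataset, mode: str) -> list[CaseStatus]:
    return ascertain_cohort(
        dataset.persons,
        dataset.events,
        dataset.labs,
        dataset.procedures,
        Classification(mode),
    )


def compute_risk_estimates(
    persons: Sequence[Person],
    cancers: Sequence,
    graph: PedigreeGraph,
    probands: Sequence[str],
    sites: Sequence[str],
    degrees: Sequence[int],
    alpha: float = 0.05,
    n_tests_female: int = 4,
    n_tests_male: int = 3,
) -> tuple[list[RiskEstimate], dict]:
    """Risk estimates for probands ("self") and each relative degree.

    The reference population for rates is the full person table. Returns
    the estimates and the rate tables used.
    """
    index = {p.person_id: p for p in persons}
    tables = {site: build_rate_table(persons, cancers, site) for site in sites}
    sets = relative_sets(graph, set(probands))
    groups: dict[str, list[Person]] = {"self": [index[p] for p in probands]}
    for d in degrees:
        groups[f"degree-{d}"] = [index[m] for m in sorted(sets[d].members) if m in index]

    estimates: list[RiskEstimate] = []
    for group, members in groups.items():
        for site in sites:
            if group == "self" and SITE_SEX[site] == frozenset("M"):
                continue  # proband group is all-female
            E = expected_count(members, tables[site])
            if E <= 0:
                continue
            O = observed_count(members, cancers, site)
            n_tests = bonferroni_tests(site, n_tests_female, n_tests_male)
            est = estimate_risk(O, E, n_tests, site=site, group=group, alpha=alpha)
            est.n_persons = sum(1 for m in members if m.sex in SITE_SEX[site])
            estimates.append(est)
    return estimates, tables


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all outputs to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    collector = _WarningCollector()
    logging.getLogger("famrisk").addHandler(collector)
    try:
        return _run_pipeline(config, out, collector)
    finally:
        logging.getLogger("famrisk").removeHandler(collector)


def _run_pipeline(
    config: PipelineConfig, out: Path, collector: _WarningCollector
) -> PipelineResult:
    dataset = _load(config)
    graph = _graph(dataset)
    cases = _ascertain(dataset, config.mode)

    n_women = sum(1 for p in dataset.persons if p.sex == "F")
    ascertained = [c for c in cases if c.classification == Classification(config.mode)]
    excluded = [c for c in cases if c.classification == Classification.EXCLUDED]

    try:
        probands = [
            c.person_id
            for c in ascertained
            if c.person_id in graph and has_three_generation_genealogy(graph, c.person_id)
        ]
    except Exception as exc:  # noqa: BLE001
        raise StageError("eligibility", str(exc)) from exc

    manifest: dict = {
        "famrisk_version": __version__,
        "seed": config.simulate.seed if config.simulate else None,
        "funnel": {
            "persons": len(dataset.persons),
            "women_screened": n_women,
            "cases_ascertained": len(ascertained) + len(excluded),
            "cases_excluded": len(excluded),
            "cases_retained": len(ascertained),
            "probands_with_3gen_genealogy": len(probands),
        },
        "warnings": [],
    }

    # cases.tsv regardless of downstream feasibility
    pd.DataFrame(
        [
            {
                "person_id": c.person_id,
                "classification": c.classification.value,
                "index_date": c.index_date.isoformat() if c.index_date else "",
                "exclusion_reason": c.exclusion_reason.value if c.exclusion_reason else "",
            }
            for c in cases
        ]
    ).to_csv(out / "cases.tsv", sep="\t", index=False)

    if config.simulate is not None:
        write_fixture(dataset, out / "registry")

    estimates: list[RiskEstimate] = []
    ped_results: list = []
    if probands:
        try:
            sets = relative_sets(graph, set(probands))
            for d in config.degrees:
                pd.DataFrame(
                    [
                        {
                            "person_id": m,
                            "degree": d,
                            "closest_relation": sets[d].closest[m][0].label,
                            "proband_id": sets[d].closest[m][1],
                        }
                        for m in sorted(sets[d].members)
                    ],
                    columns=["person_id", "degree", "closest_relation", "proband_id"],
                ).to_csv(out / f"relatives_degree{d}.tsv", sep="\t", index=False)
                manifest["funnel"][f"relatives_degree{d}"] = len(sets[d].members)
        except Exception as exc:  # noqa: BLE001
            raise StageError("relatives", str(exc)) from exc

        try:
            estimates, tables = compute_risk_estimates(
                dataset.persons,
                dataset.cancers,
                graph,
                probands,
                config.sites,
                config.degrees,
                config.alpha,
                config.n_tests_female,
                config.n_tests_male,
            )
            pd.DataFrame(estimates_to_rows(estimates, mask=False)).to_csv(
                out / "risk_estimates.tsv", sep="\t", index=False
            )
            if config.mask:
                pd.DataFrame(estimates_to_rows(estimates, mask=True)).to_csv(
                    out / "risk_estimates_masked.tsv", sep="\t", index=False
                )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("risk", str(exc)) from exc

        try:
            index = {p.person_id: p for p in dataset.persons}
            ped_results = detect_high_risk(
                graph,
                probands,
                index,
                dataset.cancers,
                tables,
                alpha=config.pedigree_alpha,
                ancestors_only=config.ancestors_only,
            )
            pd.DataFrame(results_to_rows(ped_results)).to_csv(
                out / "pedigrees_highrisk.tsv", sep="\t", index=False
            )
            manifest["funnel"]["pedigrees_tested"] = len({r.pedigree_id for r in ped_results})
            manifest["funnel"]["pedigrees_high_risk"] = len(
                {r.pedigree_id for r in ped_results if r.high_risk}
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("pedigrees", str(exc)) from exc

    manifest["warnings"] = collector.messages
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        dataset=dataset,
        graph=graph,
        cases=cases,
        probands=probands,
        estimates=estimates,
        pedigree_results=ped_results,
        manifest=manifest,
    )
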