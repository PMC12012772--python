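"""High-risk cancer pedigree detection.

A proband's pedigree is her connected genealogical set: every recorded
ancestor plus all descendants of those ancestors (which includes the
proband, her siblings, cousins, etc.). Married-in spouses who are not
descendants of a proband ancestor are not members. An ancestors-only mode
restricts the set to the proband and her direct ancestors.

For each pedigree and cancer site, the observed case count among members is
compared to the stratum-matched expected count (sum of members' reference
rates) with a one-sided upper-tail exact Poisson test; pedigrees with
p < alpha are flagged high risk, with no correction across pedigrees.
Probands sharing the same member set (e.g. sisters) share one pedigree id
and one result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pedigree import PedigreeGraph, has_three_generation_genealogy
from .records import Person
from .risk import RateTable, expected_count, observed_count, poisson_one_sided_p


@dataclass
class PedigreeExcessResult:
    pedigree_id: str
    cancer_site: str
    probands: list[str]
    member_count: int
    observed: int
    expected: float
    p_one_sided: float
    high_risk: bool
    co_excess_sites: list[str] = field(default_factory=list)


def pedigree_members(
    graph: PedigreeGraph,
    proband: str,
    ancestors_only: bool = False,
    require_three_generations: bool = True,
) -> set[str]:
    """Member set of a proband's pedigree (proband included).

    By default the proband must have three generations of genealogy (the
    familial-analysis eligibility rule); an ineligible proband raises
    ValueError. Pass ``require_three_generations=False`` to enumerate the
    connected set of a shallow pedigree anyway.
    """
    if proband not in graph:
        raise KeyError(proband)
    if require_three_generations and not has_three_generation_genealogy(graph, proband):
        raise ValueError(
            f"proband {proband} lacks 3-generation genealogy (needs both parents and all grandparents)"
        )
    ancestors = set(graph.ancestors(proband))
    if ancestors_only:
        return ancestors | {proband}
    return ancestors | graph.descendants(ancestors) | {proband}


def detect_high_risk(
    graph: PedigreeGraph,
    probands: Iterable[str],
    persons_by_id: Mapping[str, Person],
    cancer_records: Sequence,
    rate_tables: Mapping[str, RateTable],
    alpha: float = 0.05,
    ancestors_only: bool = False,
) -> list[PedigreeExcessResult]:
    """One excess test per (pedigree, site) over all eligible probands.

    Probands with identical member sets collapse into one pedigree. Results
    are ordered by pedigree id then site, independent of proband order.
    """
    by_members: dict[frozenset[str], list[str]] = {}
    for proband in sorted(set(probands)):
        members = frozenset(pedigree_members(graph, proband, ancestors_only))
        by_members.setdefault(members, []).append(proband)

    pedigrees = sorted(by_members.items(), key=lambda kv: min(kv[0]))
    results: list[PedigreeExcessResult] = []
    for idx, (members, peds_probands) in enumerate(pedigrees, start=1):
        pedigree_id = f"K{idx:04d}"
        member_persons = [persons_by_id[m] for m in sorted(members) if m in persons_by_id]
        per_site: list[PedigreeExcessResult] = []
        for site, table in sorted(rate_tables.items()):
            expected = expected_count(member_persons, table)
            if expected <= 0:
                continue
            observed = observed_count(member_persons, cancer_records, site)
            p = poisson_one_sided_p(observed, expected)
            per_site.append(
                PedigreeExcessResult(
                    pedigree_id=pedigree_id,
                    cancer_site=site,
                    probands=list(peds_probands),
                    member_count=len(members),
                    observed=observed,
                    expected=expected,
                    p_one_sided=p,
                    high_risk=p < alpha,
                )
            )
        flagged = [r.cancer_site for r in per_site if r.high_risk]
        if len(flagged) >= 2:
            for r in per_site:
                if r.high_risk:
                    r.co_excess_sites = [s for s in flagged if s != r.cancer_site]
        results.extend(per_site)
    return results


def results_to_rows(results: Iterable[PedigreeExcessResult]) -> list[dict[str, object]]:
    return [
        {
            "pedigree_id": r.pedigree_id,
            "site": r.cancer_site,
            "probands": ";".join(r.probands),
            "member_count": r.member_count,
            "observed": r.observed,
            "expected": round(r.expected, 4),
            "p": r.p_one_sided,
            "high_risk": r.high_risk,
            "co_excess_sites": ";".join(r.co_excess_sites),
        }
        for r in results
    ]
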