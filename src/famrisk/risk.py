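"""Stratified observed/expected relative risks with exact Poisson inference.

The familial relative risk is a standardized incidence ratio: the observed
cancer count O in a group divided by the expected count E obtained by
indirect standardization — each group member contributes the cumulative
cancer rate of their stratum (sex × 5-year birth cohort × Utah/non-Utah
birthplace) in an internal reference population, and E is the sum of those
contributions. Rates are cumulative (cases / cohort size), not
person-time incidence densities.

Inference treats O as Poisson with mean E under the null RR = 1:

* two-sided p — the minimum-likelihood ("minlike") exact construction,
  summing Poisson(E) probabilities of every outcome no more likely than the
  observed one (with a multiplicative tie tolerance of 1 + 1e-7 to absorb
  floating-point ties), not tail doubling;
* one-sided excess p — the upper tail P(X >= O);
* 95% CI — Garwood exact (gamma-quantile) bounds on O, divided by E.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .records import Person
from .sites import SITE_SEX, site_of_code

logger = logging.getLogger(__name__)

#: multiplicative tie tolerance of the minlike two-sided test
MINLIKE_TIE_EPS = 1e-7


@dataclass(frozen=True)
class Stratum:
    """Sex × 5-year birth cohort × binary birthplace class."""

    sex: str  # "M" / "F"
    cohort_start: int  # multiple of 5
    birthplace: str  # "UTAH" / "NON_UTAH"

    def __post_init__(self) -> None:
        if self.cohort_start % 5 != 0:
            raise ValueError(f"cohort start {self.cohort_start} not on the 5-year grid")

    def __str__(self) -> str:
        return f"{self.sex}|{self.cohort_start}|{self.birthplace}"


def assign_stratum(person: Person) -> Stratum:
    """Map a person to their rate stratum.

    The 5-year cohort is 5*floor(birth_year/5), so boundary years start
    their own bin. An unknown birthplace falls back to NON_UTAH with a
    logged warning rather than dropping the person.
    """
    if person.birth_year is None:
        raise ValueError(f"person {person.person_id}: birth year required for stratification")
    birthplace = person.birthplace
    if birthplace not in ("UTAH", "NON_UTAH"):
        logger.warning(
            "person %s: unknown birthplace %r, assigned NON_UTAH", person.person_id, birthplace
        )
        birthplace = "NON_UTAH"
    return Stratum(person.sex, 5 * (person.birth_year // 5), birthplace)


@dataclass
class RateTable:
    """Per-stratum cumulative cancer rates for one site.

    ``provenance`` keeps the reference-population tallies (cases, size) the
    rates were derived from; ``pooled_rate`` is the all-strata fallback used
    for persons whose stratum is absent from the reference.
    """

    site: str
    rates: dict[Stratum, float] = field(default_factory=dict)
    provenance: dict[Stratum, tuple[int, int]] = field(default_factory=dict)
    pooled_rate: float = 0.0

    @property
    def total_cases(self) -> int:
        return sum(c for c, _ in self.provenance.values())

    @property
    def total_reference(self) -> int:
        return sum(n for _, n in self.provenance.values())


def eligible_for_site(person: Person, site: str) -> bool:
    return person.sex in SITE_SEX[site]


def build_rate_table(
    reference_persons: Sequence[Person],
    cancer_records: Iterable,
    site: str,
) -> RateTable:
    """Tally per-stratum cumulative rates from a reference population.

    The reference is restricted to the sexes the site is analyzed in.
    A stratum's rate is (distinct persons with >= 1 record of the site) /
    (stratum size); empty strata are absent from the table.
    """
    eligible = [p for p in reference_persons if eligible_for_site(p, site)]
    if not eligible:
        raise ValueError(f"empty reference population for site {site!r}")
    eligible_ids = {p.person_id for p in eligible}
    cases = {
        r.person_id
        for r in cancer_records
        if site_of_code(r.seer_code) == site and r.person_id in eligible_ids
    }
    sizes: dict[Stratum, int] = {}
    counts: dict[Stratum, int] = {}
    for p in eligible:
        s = assign_stratum(p)
        sizes[s] = sizes.get(s, 0) + 1
        if p.person_id in cases:
            counts[s] = counts.get(s, 0) + 1
    table = RateTable(site=site)
    for s, n in sizes.items():
        c = counts.get(s, 0)
        table.rates[s] = c / n
        table.provenance[s] = (c, n)
    table.pooled_rate = len(cases) / len(eligible)
    return table


def expected_count(persons: Sequence[Person], rate_table: RateTable) -> float:
    """Indirectly standardized expected count: sum of members' stratum rates.

    Persons whose stratum is missing from the table contribute the pooled
    reference rate (logged); sex-ineligible persons contribute nothing.
    """
    total = 0.0
    n_fallback = 0
    for p in persons:
        if not eligible_for_site(p, rate_table.site):
            continue
        s = assign_stratum(p)
        rate = rate_table.rates.get(s)
        if rate is None:
            rate = rate_table.pooled_rate
            n_fallback += 1
        total += rate
    if n_fallback:
        logger.warning(
            "%d person(s) in strata absent from the %s rate table; pooled rate applied",
            n_fallback,
            rate_table.site,
        )
    return total


# -- exact Poisson inference ------------------------------------------------


def _support(E: float, O: int) -> np.ndarray:
    # outcomes beyond E + 10*sqrt(E) + 50 carry negligible mass at any E used here
    hi = int(math.ceil(E + 10.0 * math.sqrt(E) + 50.0))
    return np.arange(0, max(hi, O) + 1)


def poisson_two_sided_p(O: int, E: float) -> float:
    """Minimum-likelihood exact two-sided p-value for O ~ Poisson(E).

    Sums P(X = x) over every outcome x whose null probability does not
    exceed P(X = O) * (1 + 1e-7). When O is the modal outcome every outcome
    qualifies and p = 1.
    """
    if E <= 0:
        raise ValueError(f"expected count must be positive, got {E}")
    if O < 0 or O != int(O):
        raise ValueError(f"observed count must be a non-negative integer, got {O}")
    O = int(O)
    xs = _support(E, O)
    pmf = stats.poisson.pmf(xs, E)
    p = float(pmf[pmf <= pmf[O] * (1.0 + MINLIKE_TIE_EPS)].sum())
    return min(p, 1.0)


def poisson_one_sided_p(O: int, E: float) -> float:
    """Upper-tail excess p-value P(X >= O) for O ~ Poisson(E)."""
    if E <= 0:
        raise ValueError(f"expected count must be positive, got {E}")
    if O < 0 or O != int(O):
        raise ValueError(f"observed count must be a non-negative integer, got {O}")
    return float(stats.poisson.sf(int(O) - 1, E))


def poisson_exact_ci(O: int, E: float, level: float = 0.95) -> tuple[float, float]:
    """Garwood exact confidence bounds on RR = O/E.

    low = gamma-quantile(alpha/2; shape O) / E (0 when O = 0);
    high = gamma-quantile(1 - alpha/2; shape O + 1) / E.
    """
    if E <= 0:
        raise ValueError(f"expected count must be positive, got {E}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    O = int(O)
    alpha = 1.0 - level
    low = 0.0 if O == 0 else float(stats.gamma.ppf(alpha / 2.0, O)) / E
    high = float(stats.gamma.ppf(1.0 - alpha / 2.0, O + 1)) / E
    return low, high


@dataclass
class RiskEstimate:
    """One familial relative-risk result: a cancer site in one group."""

    site: str
    group: str  # "self" / "degree-1" / "degree-2" / "degree-3" / ...
    observed: int
    expected: float
    rr: float
    ci_low: float
    ci_high: float
    p: float
    bonferroni_alpha: float
    significant: bool
    n_persons: int = 0


def estimate_risk(
    O: int,
    E: float,
    n_tests: int,
    site: str = "",
    group: str = "",
    alpha: float = 0.05,
    level: float = 0.95,
    n_persons: int = 0,
) -> RiskEstimate:
    """Assemble RR = O/E with exact CI, minlike two-sided p and Bonferroni flag."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    ci_low, ci_high = poisson_exact_ci(O, E, level)
    p = poisson_two_sided_p(O, E)
    threshold = alpha / n_tests
    return RiskEstimate(
        site=site,
        group=group,
        observed=int(O),
        expected=E,
        rr=O / E,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        bonferroni_alpha=threshold,
        significant=p < threshold,
        n_persons=n_persons,
    )


def observed_count(persons: Sequence[Person], cancer_records: Iterable, site: str) -> int:
    """Distinct sex-eligible persons in the group with >= 1 record of the site."""
    ids = {p.person_id for p in persons if eligible_for_site(p, site)}
    return len({r.person_id for r in cancer_records if site_of_code(r.seer_code) == site and r.person_id in ids})


def mask_count(count: int, threshold: int = 10) -> str:
    """Small-cell disclosure masking: counts <= threshold print as "<=10"."""
    return f"<={threshold}" if count <= threshold else str(count)


def estimates_to_rows(
    estimates: Iterable[RiskEstimate], mask: bool = False
) -> list[dict[str, object]]:
    """Rows for risk_estimates.tsv; masking affects display only."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "site": e.site,
                "group": e.group,
                "n_persons": e.n_persons,
                "observed": mask_count(e.observed) if mask else e.observed,
                "expected": round(e.expected, 4),
                "rr": round(e.rr, 4),
                "ci_low": round(e.ci_low, 4),
                "ci_high": round(e.ci_high, 4),
                "p": e.p,
                "alpha": e.bonferroni_alpha,
                "significant": e.significant,
            }
        )
    return rows
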