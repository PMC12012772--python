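# Methods

## Study design the package implements

The analysis is a population-based familial-aggregation design. Probands
are women ascertained with primary ovarian insufficiency (POI) from coded
EMR data; their relatives are enumerated from genealogy; cancer outcomes
come from a registry table keyed by SEER site recodes (breast 26000,
corpus uteri 27020–27030, ovary 27040, prostate 28010, testis 28020,
cecum–sigmoid colon 21041–21046). Risk is quantified as a standardized
incidence ratio O/E with indirect standardization: each group member
contributes the cumulative cancer rate of their stratum in an internal
reference population, and the sum of those contributions is the expected
count. Rates are *cumulative* (cases divided by cohort size), not
person-time incidence densities: there is no follow-up time, censoring or
competing-risk structure anywhere in the model, and the simulator
deliberately mirrors this cumulative-risk framing with one lifetime
Bernoulli outcome per person and site.

## Case ascertainment

A woman qualifies as a POI case on the earliest of: a POI diagnosis code
(ICD-9 256.3, 256.31, 256.39; ICD-10 E28.3, E28.31, E28.39, E28.310,
E28.319) recorded at completed age ≤ 40, or FSH > 20 IU/L, or
AMH < 0.08 ng/mL inside the same window. Early-menopause mode uses
40 < age < 45. Decisions taken where the definitions leave room:

* **Strict thresholds.** The lab criteria are strict inequalities exactly
  as stated; FSH = 20.0 does not qualify. No rounding rule is applied.
* **Earliest-evidence index.** When code- and lab-based dates differ, the
  index date is the earliest qualifying record of either kind; the
  evidence list in the output records every qualifying item so the choice
  is auditable.
* **Ages in completed years** from birth year only (event year − birth
  year), since registry extracts usually carry birth year, not birth date.
* **Exclusion timing.** Hysterectomy, oophorectomy, endometriosis with
  pelvic surgery, pelvic radiation and chemotherapy exclude only when they
  precede the index date. Turner syndrome (ICD-9 758.6, ICD-10 Q96.*)
  excludes at any date: it is congenital, so the date qualifier that makes
  sense for acquired/surgical exclusions does not apply.
* **Chart review** is represented only as an optional per-person boolean
  verdict that can demote an ascertained case; the adjudication itself is
  human and not modeled.

## Pedigree analysis

The genealogy is a directed parent→child graph parsed from 6-column PED.
Eligibility for familial analysis requires three generations on record:
both parents and all four grandparents (equivalently ≥ 6 distinct
ancestors within depth 2).

Relationship classification follows the enumerated relative types:
first degree — parent, child, sibling; second — grandparent, grandchild,
aunt/uncle, niece/nephew, half-sibling; third — great-grandparent,
great-grandchild, first cousin. The lists are treated as exhaustive:
great-aunts, grand-nephews, half-first-cousins, half-aunts and every other
unenumerated connection classify as OTHER and are excluded from all sets.
Consequently aunt/uncle, niece/nephew and first-cousin links require
*full*-sibling connections. Classification uses the closest genealogical
path (relevant in inbred loops), with ties broken toward the lower degree;
SIBLING requires both parents shared, HALF_SIBLING exactly one.

Relative sets are deduplicated two ways: a person related to several
probands is counted once, and a person qualifying at more than one degree
is kept only in the lowest-degree set, so the three sets partition the
counted relatives and no cancer case can be counted in two risk groups.
Relative-set assembly walks the graph constructively (parents, siblings'
children, parents' full siblings, …); the exhaustive pairwise
classification of every (proband, person) pair is kept as an independent
oracle in the test suite rather than being the implementation.

## Rates, expected counts and exact inference

Strata are sex × 5-year birth cohort (5·⌊year/5⌋, so boundary years open
their own bin) × binary birthplace (Utah / non-Utah; unknown birthplace
falls back to non-Utah with a logged warning rather than dropping the
person). Sex-specific sites restrict both the reference population and the
analyzed group to the relevant sex; breast is analyzed in women only,
colon in both sexes.

A rate table records per-stratum cumulative rates with their provenance
tallies. Group members whose stratum is absent from the reference
contribute the pooled all-strata rate (logged); dropping them would
silently deflate E. Applying a table back to its own reference population
returns exactly the total observed case count — a conservation identity
the tests enforce per site.

Exact inference, all under O ~ Poisson(E):

* **Two-sided p** is the minimum-likelihood construction: the sum of
  Poisson(E) probabilities over every outcome whose likelihood does not
  exceed that of the observed count, with a multiplicative tie tolerance
  of 1 + 1e-7 to absorb floating-point ties. Tail doubling was rejected
  because it cannot reproduce the benchmark values this engine is
  validated against (e.g. for O=18, E=8.19 the upper tail is ≈ .0020 and
  the opposite-tail outcome set {0} adds ≈ .0003, giving .0023; doubling
  gives .0041). When O is the modal outcome every outcome qualifies and
  p = 1. The support is enumerated to E + 10√E + 50, beyond which the
  omitted mass is far below the 1e-10 oracle tolerance for all E in use.
* **CI** is the Garwood exact interval on the count divided by E:
  low = gamma-quantile(α/2, shape O)/E (0 when O = 0),
  high = gamma-quantile(1−α/2, shape O+1)/E. For O ≥ 1 the interval always
  brackets O/E, and width shrinks as counts grow at fixed RR.
* **One-sided excess p** is the plain upper tail P(X ≥ O), used for
  pedigree screening.
* **Multiplicity**: Bonferroni divisors are per sex — default 4 for sites
  analyzed in women (breast, ovary, uterus and colon, the latter tested in
  both sexes) and 3 for male-only sites (prostate, testis) — applied to a
  base α of 0.05.

## High-risk pedigrees

A proband's pedigree is her connected genealogical set: all recorded
ancestors plus every descendant of those ancestors. Married-in spouses who
are not themselves descendants of a proband ancestor are excluded; an
ancestors-only mode is provided because the member set behind this kind of
screening is genuinely ambiguous in practice, and the full-pedigree mode
is the default because ancestors alone cannot produce the large observed
counts this screening targets. Each (pedigree, site) pair gets a one-sided
excess test at α = 0.05 with no correction across pedigrees; pedigrees
with two or more sites in excess have the co-excess sites listed.
Probands with identical member sets (sisters) share one pedigree id and
one result. The eligibility rule (three generations) is enforced by
default and can be lifted for exploratory use on shallow pedigrees.

## Synthetic registry generator

The generator emulates the linked genealogy–EMR–registry data model so
every downstream stage can be tested against known truth.

* **Mating model**: strictly monogamous, non-consanguineous. Founder
  couples (default 80) start generation 0 with birth years uniform in
  1920–1935; each couple has Poisson-distributed children (mean 2.6, a
  realistic completed family size for this kind of multi-generation Utah
  genealogy) with generational gaps uniform in 20–35 years; children marry
  spawned unrelated spouses. Marry-ins carry their own recorded parents —
  without that, no descendant would ever have four recorded grandparents
  and the three-generation rule would select nobody. Half-siblings are
  injected only via the explicit second-union option (default off), so
  relationship ground truth stays unambiguous.
* **Default depth** is 4 generations (minimum 3), giving a pool of
  probands that satisfy the eligibility rule.
* **POI**: assigned to women with prevalence 0.011 (within the accepted
  ~1% population prevalence of POI), onset age uniform 18–40; every
  carrier receives both a qualifying ICD-10 code and an elevated FSH at
  onset, so ascertainment sensitivity and specificity are 1 by
  construction on clean data.
* **Cancer**: one Bernoulli draw per person and site with probability
  baseline stratum rate × familial multiplier, capped at 1. Default
  lifetime rates (breast 0.12, prostate 0.12, colon 0.04, uterus 0.03,
  ovary 0.012, testis 0.004) are order-of-magnitude realistic for a US
  registry population. Baseline rates accept either a scalar per site or a
  stratum-pattern map ("SEX|COHORT|PLACE" with coarser fallbacks), so
  stratum-varying baselines can be planted. Multipliers are keyed
  "site:degree" with degree 0 the carrier herself; a person related to
  several carriers takes the single largest applicable multiplier —
  effects never compound, matching the analysis model, which estimates one
  multiplier per (site, degree).
* **Determinism**: one seeded generator drives every draw; a config
  without a seed is rejected. Identical configs and seeds give
  byte-identical written fixtures.
* **Birthplace**: Bernoulli Utah-born with probability 0.75, roughly the
  share of Utah-born members in a genealogy anchored on Utah founders.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: mortality and censoring (everyone is
observed for life), migration, realistic age-at-onset distributions
(uniform draws only), secular trends in cancer incidence beyond whatever
is planted per stratum, record-linkage errors, diagnostic miscoding, and
EMR free-text evidence. Results on real registry data additionally depend
on linkage quality and chart-review accuracy, which are out of scope.

## Numerical and design notes

* Minlike enumeration is vectorized over the truncated support; the test
  oracle re-derives it with pure-python log-gamma sums so the two routes
  are independent.
* The one-sided test is scipy's Poisson survival function; the CI uses
  gamma quantiles. Degenerate inputs (E ≤ 0, negative or non-integer O,
  empty reference populations, empty proband sets) raise ValueError rather
  than returning sentinel values.
* The discrete one-sided test is conservative: its attained size at
  α = 0.05 is P(X ≥ x*) < 0.05 and oscillates with E. The calibration
  test therefore compares the empirical flag rate on null simulations
  against the analytic attained size at each pedigree's E (within
  Monte-Carlo error, and bounded above by nominal + Monte-Carlo error),
  rather than pretending a discrete test attains 5% exactly. Simulated
  pedigrees were sized so most expected counts sit in a regime where the
  attained size is near nominal.
* Simulation-based tests and the acceptance script use moderate problem
  sizes (populations of roughly 2,000–30,000 persons, 30–100 replicates)
  — large enough for the binomial/Poisson error bands they assert, small
  enough to keep the default suite fast on one CPU.
* Masked report output prints counts ≤ 10 as "<=10", mirroring registry
  small-cell disclosure rules; masking is display-only and never feeds
  back into computation.

## Known limitations

* No person-time SIR, competing risks, or regression modeling — the
  cumulative-rate design is the model, by construction.
* Relative counts deduplicate across probands; analyses that instead count
  a relative once per proband will differ.
* The ovarian benchmark row with a disclosure-masked observed count is not
  reproducible from its printed interval by any integer O consistent with
  its RR; masked rows are therefore excluded from engine validation.
* Inbreeding loops are classified on the shortest path only; kinship
  coefficients and identity-by-descent are out of scope.
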