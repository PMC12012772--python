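"""Published benchmark inputs for the statistical engine.

Observed/expected count pairs from a published population-based familial
cancer analysis of primary ovarian insufficiency (Utah genealogy + cancer
registry). Each pair is an *input*: the engine recomputes RR = O/E, the
exact minlike two-sided p, Garwood 95% bounds, and one-sided pedigree
excess p from (O, E) alone, and the recomputed values can be checked
against that study's printed estimates. Pairs with disclosure-masked
observed counts cannot serve as inputs and are not represented.
"""

from __future__ import annotations

from .risk import poisson_exact_ci, poisson_one_sided_p, poisson_two_sided_p

#: group-level (observed, expected) pairs: proband and relative-set results.
#: "self" groups are women with POI (the genealogy subset has 416 probands);
#: "poi_plus_early_menopause" adds early-menopause cases (778 women total).
RELATIVE_RISK_PAIRS: dict[str, tuple[int, float]] = {
    "proband_breast": (18, 8.19),
    "poi_plus_early_menopause_breast": (23, 12.15),
    "genealogy_proband_breast": (13, 5.30),
    "first_degree_breast": (32, 26.42),
    "first_degree_prostate": (41, 24.96),
    "second_degree_breast": (127, 99.58),
    "second_degree_ovary": (12, 12.39),
    "second_degree_colon": (58, 38.71),
    "second_degree_uterus": (25, 23.53),
    "second_degree_prostate": (174, 112.72),
    "third_degree_breast": (230, 227.36),
    "third_degree_ovary": (37, 30.76),
    "third_degree_colon": (123, 111.53),
    "third_degree_uterus": (49, 58.24),
    "third_degree_prostate": (364, 272.94),
    "third_degree_testis": (11, 10.23),
}

#: (observed, expected) for single high-risk pedigrees (one-sided excess).
PEDIGREE_EXCESS_PAIRS: dict[str, tuple[int, float]] = {
    "pedigree_breast_1": (70, 46.79),
    "pedigree_breast_2": (33, 19.48),
    "pedigree_colorectal_7": (48, 28.80),
    "pedigree_ovary_13": (12, 3.17),
    "pedigree_prostate_17": (143, 110.24),
}


def engine_report() -> dict[str, dict[str, float | int]]:
    """Recompute every benchmark quantity from its (O, E) input pair.

    Returns {name: {value, n}} entries: per relative-risk pair the RR,
    two-sided p and CI bounds; per pedigree pair the one-sided excess p.
    All values are computed at call time by the inference engine.
    """
    out: dict[str, dict[str, float | int]] = {}
    for name, (O, E) in RELATIVE_RISK_PAIRS.items():
        lo, hi = poisson_exact_ci(O, E)
        out[f"{name}_rr"] = {"value": round(O / E, 4), "n": O}
        out[f"{name}_p"] = {"value": poisson_two_sided_p(O, E), "n": O}
        out[f"{name}_ci_low"] = {"value": round(lo, 4), "n": O}
        out[f"{name}_ci_high"] = {"value": round(hi, 4), "n": O}
    for name, (O, E) in PEDIGREE_EXCESS_PAIRS.items():
        out[f"{name}_p"] = {"value": poisson_one_sided_p(O, E), "n": O}
    return out
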