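"""Cancer site coding.

Sites are identified by SEER numeric site recodes. Each site carries the set
of sexes it is analyzed in: sex-specific sites (breast, ovary, uterus in
women; prostate, testis in men) restrict both the reference population used
for rates and the relative sets counted against them, while colon/colorectal
is analyzed in both sexes.
"""

from __future__ import annotations

BREAST = "breast"
OVARY = "ovary"
UTERUS = "uterus"
COLON = "colon"
PROSTATE = "prostate"
TESTIS = "testis"

ALL_SITES = (BREAST, OVARY, UTERUS, COLON, PROSTATE, TESTIS)

#: SEER site recode ranges (inclusive) per site.
SEER_CODES: dict[str, tuple[int, int]] = {
    BREAST: (26000, 26000),
    UTERUS: (27020, 27030),  # corpus uteri
    OVARY: (27040, 27040),
    PROSTATE: (28010, 28010),
    TESTIS: (28020, 28020),
    COLON: (21041, 21046),  # cecum through sigmoid
}

#: Sexes a site is analyzed in.
SITE_SEX: dict[str, frozenset[str]] = {
    BREAST: frozenset("F"),
    OVARY: frozenset("F"),
    UTERUS: frozenset("F"),
    PROSTATE: frozenset("M"),
    TESTIS: frozenset("M"),
    COLON: frozenset("MF"),
}

#: Representative SEER code used when a single code must be emitted.
CANONICAL_CODE: dict[str, int] = {s: lo for s, (lo, hi) in SEER_CODES.items()}

FEMALE_SITES = tuple(s for s in ALL_SITES if "F" in SITE_SEX[s])
MALE_SITES = tuple(s for s in ALL_SITES if "M" in SITE_SEX[s])


def site_of_code(code: int) -> str | None:
    """Map a SEER site recode to a site label, or None if untracked."""
    for site, (lo, hi) in SEER_CODES.items():
        if lo <= code <= hi:
            return site
    return None


def bonferroni_tests(site: str, n_female_sites: int = 4, n_male_sites: int = 3) -> int:
    """Number of tests the per-site significance threshold divides alpha by.

    Sites analyzed in women (including colon, tested in both sexes) use the
    female divisor; male-only sites use the male divisor.
    """
    if site not in SITE_SEX:
        raise ValueError(f"unknown site: {site!r}")
    return n_female_sites if "F" in SITE_SEX[site] else n_male_sites
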