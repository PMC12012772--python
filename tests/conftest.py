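"""Shared fixtures: a hand-built multi-generation pedigree and simulated registries."""

from __future__ import annotations

import math

import pytest

from famrisk.pedigree import parse_ped
from famrisk.simulate import SimConfig, simulate_population

# Four-generation family covering every enumerated relative type, from the
# viewpoint of proband PRO:
#   great-grandparents GGF/GGM -> grandfather GF (and his brother GUNC, a
#   great-uncle to PRO); GF x GM -> father FA, aunt AU; FA x MO -> PRO,
#   sister SIB, half-brother HSIB (FA x MO2); AU x AUH -> cousin CUZ (and
#   CUZ's child CUZK, unenumerated); SIB x SIBH -> niece NIE; PRO x SPO ->
#   child KID -> grandchild GKID -> great-grandchild GGKID.
TOY_PED = """\
F1 GGF 0   0   1 0
F1 GGM 0   0   2 0
F1 GF  GGF GGM 1 0
F1 GUNC GGF GGM 1 0
F1 GM  0   0   2 0
F1 FA  GF  GM  1 0
F1 AU  GF  GM  2 0
F1 MO  0   0   2 0
F1 MO2 0   0   2 0
F1 AUH 0   0   1 0
F1 PRO FA  MO  2 0
F1 SIB FA  MO  2 0
F1 HSIB FA MO2 1 0
F1 CUZ AUH AU  2 0
F1 CUZK 0  CUZ 1 0
F1 SIBH 0  0   1 0
F1 NIE SIBH SIB 2 0
F1 SPO 0   0   1 0
F1 KID SPO PRO 2 0
F1 KIDH 0  0   1 0
F1 GKID KIDH KID 1 0
F1 GKIDW 0 0   2 0
F1 GGKID GKID GKIDW 2 0
"""


@pytest.fixture(scope="session")
def toy_graph():
    return parse_ped(TOY_PED)


@pytest.fixture(scope="session")
def null_dataset():
    """Moderate null registry: no familial effect (all multipliers 1)."""
    cfg = SimConfig(n_founder_couples=40, n_generations=4, seed=20240)
    return simulate_population(cfg)


def minlike_oracle(O: int, E: float, eps: float = 1e-7) -> float:
    """Independent brute-force minlike p: pure-python log-gamma enumeration."""
    hi = max(int(math.ceil(E + 10.0 * math.sqrt(E) + 50.0)), O)
    logp_obs = O * math.log(E) - E - math.lgamma(O + 1)
    cutoff = logp_obs + math.log1p(eps)
    total = 0.0
    for x in range(hi + 1):
        logp = x * math.log(E) - E - math.lgamma(x + 1)
        if logp <= cutoff:
            total += math.exp(logp)
    return min(total, 1.0)


def upper_tail_oracle(O: int, E: float) -> float:
    """Independent brute-force upper tail P(X >= O) via the complement."""
    if O == 0:
        return 1.0
    below = sum(math.exp(x * math.log(E) - E - math.lgamma(x + 1)) for x in range(O))
    return 1.0 - below
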