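"""Genealogy graph, relationship classification and relative-set assembly.

The genealogical degree of a relative determines which risk group they are
counted in:

* first degree — parents, siblings, children;
* second degree — grandparents, aunts/uncles, nieces/nephews, half-siblings,
  grandchildren;
* third degree — great-grandparents, great-grandchildren, first cousins.

These enumerations are treated as exhaustive: relative types they do not
name (great-aunts/uncles, grand-nieces/nephews, half-first-cousins,
half-aunts, ...) classify as OTHER and are excluded from every set.
Aunt/uncle, niece/nephew and first-cousin links therefore require *full*
sibling connections.

Probands are eligible for familial analysis only with three generations of
genealogy recorded: both parents and all four grandparents (equivalently,
six or more distinct ancestors within depth two).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable

import networkx as nx


class RelationType(enum.Enum):
    """Relation of person b to person a, with genealogical degree."""

    PARENT = ("PARENT", 1)
    CHILD = ("CHILD", 1)
    SIBLING = ("SIBLING", 1)
    GRANDPARENT = ("GRANDPARENT", 2)
    GRANDCHILD = ("GRANDCHILD", 2)
    AUNT_UNCLE = ("AUNT_UNCLE", 2)
    NIECE_NEPHEW = ("NIECE_NEPHEW", 2)
    HALF_SIBLING = ("HALF_SIBLING", 2)
    GREAT_GRANDPARENT = ("GREAT_GRANDPARENT", 3)
    GREAT_GRANDCHILD = ("GREAT_GRANDCHILD", 3)
    FIRST_COUSIN = ("FIRST_COUSIN", 3)
    OTHER = ("OTHER", None)

    def __init__(self, label: str, degree: int | None):
        self.label = label
        self.degree = degree


#: role inversion under swapping (a, b)
INVERSE: dict[RelationType, RelationType] = {
    RelationType.PARENT: RelationType.CHILD,
    RelationType.CHILD: RelationType.PARENT,
    RelationType.GRANDPARENT: RelationType.GRANDCHILD,
    RelationType.GRANDCHILD: RelationType.GRANDPARENT,
    RelationType.AUNT_UNCLE: RelationType.NIECE_NEPHEW,
    RelationType.NIECE_NEPHEW: RelationType.AUNT_UNCLE,
    RelationType.GREAT_GRANDPARENT: RelationType.GREAT_GRANDCHILD,
    RelationType.GREAT_GRANDCHILD: RelationType.GREAT_GRANDPARENT,
    RelationType.SIBLING: RelationType.SIBLING,
    RelationType.HALF_SIBLING: RelationType.HALF_SIBLING,
    RelationType.FIRST_COUSIN: RelationType.FIRST_COUSIN,
    RelationType.OTHER: RelationType.OTHER,
}


class PedFormatError(ValueError):
    """Malformed or inconsistent PED input."""


class PedigreeGraph:
    """Directed parent→child genealogy.

    Nodes are person ids with sex; each child has at most one father and one
    mother. The graph must be acyclic (no one is their own ancestor).
    """

    def __init__(self) -> None:
        self.sex: dict[str, str] = {}  # "M" / "F" / "U"
        self.father: dict[str, str] = {}
        self.mother: dict[str, str] = {}
        self.children: dict[str, set[str]] = {}
        self.family: dict[str, str] = {}

    # -- construction ------------------------------------------------------

    def add_individual(self, pid: str, sex: str = "U", family: str | None = None) -> None:
        prev = self.sex.get(pid)
        if prev is None or prev == "U":
            self.sex[pid] = sex
        elif sex not in ("U", prev):
            raise PedFormatError(f"individual {pid}: conflicting sex {prev} vs {sex}")
        if family is not None:
            self.family.setdefault(pid, family)

    def set_parents(self, child: str, father: str | None, mother: str | None) -> None:
        for role, parent, store, psex in (
            ("father", father, self.father, "M"),
            ("mother", mother, self.mother, "F"),
        ):
            if parent is None:
                continue
            if child in store and store[child] != parent:
                raise PedFormatError(
                    f"individual {child}: conflicting {role} {store[child]} vs {parent}"
                )
            self.add_individual(parent, psex)
            store[child] = parent
            self.children.setdefault(parent, set()).add(child)
        if father is not None and mother is not None and father == mother:
            raise PedFormatError(f"individual {child}: father and mother are the same id")

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.sex)
        for child, f in self.father.items():
            g.add_edge(f, child)
        for child, m in self.mother.items():
            g.add_edge(m, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedFormatError(f"cyclic ancestry involving {cycle[0][0]}")

    # -- queries -----------------------------------------------------------

    def __contains__(self, pid: str) -> bool:
        return pid in self.sex

    def __len__(self) -> int:
        return len(self.sex)

    @property
    def nodes(self) -> set[str]:
        return set(self.sex)

    def parents(self, pid: str) -> tuple[str | None, str | None]:
        return self.father.get(pid), self.mother.get(pid)

    def parent_set(self, pid: str) -> set[str]:
        return {p for p in self.parents(pid) if p is not None}

    def ancestors(self, pid: str, max_depth: int | None = None) -> dict[str, int]:
        """Minimal up-step depth of each ancestor (self excluded)."""
        depths: dict[str, int] = {}
        frontier = [pid]
        d = 0
        while frontier and (max_depth is None or d < max_depth):
            d += 1
            nxt: list[str] = []
            for x in frontier:
                for p in self.parents(x):
                    if p is not None and p not in depths:
                        depths[p] = d
                        nxt.append(p)
            frontier = nxt
        return depths

    def descendants(self, pids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        frontier = list(pids)
        while frontier:
            x = frontier.pop()
            for c in self.children.get(x, ()):
                if c not in out:
                    out.add(c)
                    frontier.append(c)
        return out


def parse_ped(source: str | Path | IO[str]) -> PedigreeGraph:
    """Parse 6-column whitespace-delimited PED records into a graph.

    Parent id "0" means unknown. Individuals that appear only in parent
    columns become nodes. Conflicting re-declarations (parents or sex) and
    cyclic ancestry raise :class:`PedFormatError`.
    """
    if isinstance(source, (str, Path)):
        if isinstance(source, str) and "\n" in source:
            fh: IO[str] = StringIO(source)
        else:
            fh = open(source)
    else:
        fh = source
    graph = PedigreeGraph()
    declared_parents: dict[str, tuple[str, str]] = {}
    sex_map = {"1": "M", "2": "F"}
    try:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 6:
                raise PedFormatError(f"line {ln}: expected 6 columns, got {len(fields)}")
            fam, pid, fa, mo, sx = fields[0], fields[1], fields[2], fields[3], fields[4]
            if pid in declared_parents and declared_parents[pid] != (fa, mo):
                raise PedFormatError(f"line {ln}: individual {pid} re-declared with different parents")
            declared_parents[pid] = (fa, mo)
            graph.add_individual(pid, sex_map.get(sx, "U"), family=fam)
            graph.set_parents(pid, None if fa == "0" else fa, None if mo == "0" else mo)
    finally:
        if fh is not source:
            fh.close()
    graph.validate()
    return graph


def has_three_generation_genealogy(graph: PedigreeGraph, pid: str) -> bool:
    """True iff both parents and all four grandparents are recorded.

    Equivalent to having >= 6 distinct ancestors within depth 2.
    """
    if pid not in graph:
        raise KeyError(pid)
    return len(graph.ancestors(pid, max_depth=2)) >= 6


def _sibling_kind(graph: PedigreeGraph, a: str, b: str) -> str | None:
    """"FULL" if a and b share both recorded parents, "HALF" if exactly one."""
    pa, pb = graph.parent_set(a), graph.parent_set(b)
    shared = pa & pb
    if len(shared) == 2:
        return "FULL"
    if len(shared) == 1:
        return "HALF"
    return None


def classify_relationship(graph: PedigreeGraph, a: str, b: str) -> RelationType:
    """Relation of ``b`` to ``a`` (e.g. b is a's mother → PARENT).

    Classification follows the closest genealogical connection; ties in path
    length break toward the lower degree. SIBLING requires both parents
    shared, HALF_SIBLING exactly one; aunt/uncle, niece/nephew and
    first-cousin require full-sibling links (see module docstring). Any
    unenumerated connection is OTHER.
    """
    if a == b:
        raise ValueError("cannot classify a person against themselves")
    if a not in graph or b not in graph:
        raise KeyError(f"person not in pedigree: {a if a not in graph else b}")

    anc_a = graph.ancestors(a, max_depth=3)
    anc_b = graph.ancestors(b, max_depth=3)

    # (path length, degree or 4 for OTHER, relation)
    candidates: list[tuple[int, int, RelationType]] = []

    def add(dist: int, rel: RelationType) -> None:
        candidates.append((dist, rel.degree if rel.degree is not None else 4, rel))

    lineal_up = {1: RelationType.PARENT, 2: RelationType.GRANDPARENT, 3: RelationType.GREAT_GRANDPARENT}
    lineal_down = {1: RelationType.CHILD, 2: RelationType.GRANDCHILD, 3: RelationType.GREAT_GRANDCHILD}
    if b in anc_a:
        add(anc_a[b], lineal_up[anc_a[b]])
    if a in anc_b:
        add(anc_b[a], lineal_down[anc_b[a]])

    sib = _sibling_kind(graph, a, b)
    if sib == "FULL":
        add(2, RelationType.SIBLING)
    elif sib == "HALF":
        add(2, RelationType.HALF_SIBLING)

    # b child of a full sibling of a → niece/nephew
    for pb in graph.parent_set(b):
        if pb != a and _sibling_kind(graph, a, pb) == "FULL":
            add(3, RelationType.NIECE_NEPHEW)
            break
    # b full sibling of a parent of a → aunt/uncle
    for pa in graph.parent_set(a):
        if pa != b and _sibling_kind(graph, pa, b) == "FULL":
            add(3, RelationType.AUNT_UNCLE)
            break
    # parents are full siblings → first cousins
    done = False
    for pa in graph.parent_set(a):
        for pb in graph.parent_set(b):
            if pa != pb and _sibling_kind(graph, pa, pb) == "FULL":
                add(4, RelationType.FIRST_COUSIN)
                done = True
                break
        if done:
            break

    if not candidates:
        return RelationType.OTHER
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


@dataclass
class RelativeSet:
    """Deduplicated relatives of a proband set at one genealogical degree.

    ``closest`` records, per member, one (relation, proband) pair realizing
    the member's classification at this degree.
    """

    degree: int
    members: set[str] = field(default_factory=set)
    closest: dict[str, tuple[RelationType, str]] = field(default_factory=dict)


def _relatives_by_degree(graph: PedigreeGraph, proband: str) -> dict[int, dict[str, RelationType]]:
    """Constructive enumeration of a proband's enumerated relatives.

    Walks parent/child/sibling links directly rather than classifying all
    pairs, so the exhaustive pairwise classification remains an independent
    check on this routine.
    """
    out: dict[int, dict[str, RelationType]] = {1: {}, 2: {}, 3: {}}

    def put(deg: int, pid: str, rel: RelationType) -> None:
        if pid != proband and pid not in out[deg]:
            out[deg][pid] = rel

    parents = graph.parent_set(proband)
    kids = graph.children.get(proband, set())
    fullsibs = {
        s
        for p in parents
        for s in graph.children.get(p, ())
        if s != proband and _sibling_kind(graph, proband, s) == "FULL"
    }
    halfsibs = {
        s
        for p in parents
        for s in graph.children.get(p, ())
        if s != proband and _sibling_kind(graph, proband, s) == "HALF"
    }

    for p in parents:
        put(1, p, RelationType.PARENT)
    for c in kids:
        put(1, c, RelationType.CHILD)
    for s in fullsibs:
        put(1, s, RelationType.SIBLING)

    grandparents = {gp for p in parents for gp in graph.parent_set(p)}
    for gp in grandparents:
        put(2, gp, RelationType.GRANDPARENT)
    for c in kids:
        for gc in graph.children.get(c, ()):
            put(2, gc, RelationType.GRANDCHILD)
    aunts = {
        s
        for p in parents
        for gp in graph.parent_set(p)
        for s in graph.children.get(gp, ())
        if s != p and _sibling_kind(graph, p, s) == "FULL"
    }
    for au in aunts:
        put(2, au, RelationType.AUNT_UNCLE)
    for s in fullsibs:
        for n in graph.children.get(s, ()):
            put(2, n, RelationType.NIECE_NEPHEW)
    for h in halfsibs:
        put(2, h, RelationType.HALF_SIBLING)

    for gp in grandparents:
        for ggp in graph.parent_set(gp):
            put(3, ggp, RelationType.GREAT_GRANDPARENT)
    for c in kids:
        for gc in graph.children.get(c, ()):
            for ggc in graph.children.get(gc, ()):
                put(3, ggc, RelationType.GREAT_GRANDCHILD)
    for au in aunts:
        for cz in graph.children.get(au, ()):
            put(3, cz, RelationType.FIRST_COUSIN)

    return out


def relative_set(graph: PedigreeGraph, probands: set[str], degree: int) -> RelativeSet:
    """Union of all probands' relatives at ``degree``, deduplicated.

    A person related to several probands appears once; a person qualifying
    at more than one degree is kept only in the lowest-degree set, so the
    degree-1/2/3 sets partition the counted relatives and no cancer case is
    counted in two groups. Probands are always removed.
    """
    if not probands:
        raise ValueError("proband set is empty")
    missing = probands - graph.nodes
    if missing:
        raise KeyError(f"probands not in pedigree: {sorted(missing)}")
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")

    best: dict[str, tuple[int, RelationType, str]] = {}
    for proband in sorted(probands):
        for deg, rels in _relatives_by_degree(graph, proband).items():
            for pid, rel in rels.items():
                cur = best.get(pid)
                if cur is None or deg < cur[0]:
                    best[pid] = (deg, rel, proband)

    out = RelativeSet(degree=degree)
    for pid, (deg, rel, proband) in best.items():
        if deg == degree and pid not in probands:
            out.members.add(pid)
            out.closest[pid] = (rel, proband)
    return out


def relative_sets(graph: PedigreeGraph, probands: set[str]) -> dict[int, RelativeSet]:
    """All three degree sets at once (shared lowest-degree resolution)."""
    return {d: relative_set(graph, probands, d) for d in (1, 2, 3)}
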