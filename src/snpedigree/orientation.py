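"""Assigning parent/offspring roles within accepted duos.

The exclusion tests are symmetric, so an accepted duo only says "first
degree, parent-offspring-like"; orientation decides who is the parent.
Rules are applied in strict precedence order:

1. trio membership — an individual identified as an offspring in an
   accepted trio must be the parent in any other duo it is involved in
   (it cannot have a third parent), and each newly inferred offspring
   propagates the same logic iteratively to a fixed point;
2. documented parentage — one member recorded as the other's offspring;
3. documented dates — the later-dated member is the offspring, applied
   only when both dates are present and precise and the gap is at least
   ``min_year_gap`` years;
4. propagation re-runs after the metadata passes.

Contradictions (an individual forced into both roles against the same
partner, cycles, or two date-oriented duos whose joint parents fail the
trio test) are recorded, never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .exclusion import DuoResult, TrioResult
from .genotype_io import CultivarMetadata

BASES = ("trio_membership", "propagation", "documented_parentage",
         "documented_date", "grandparent_group", "unoriented")


@dataclass
class OrientedDuo:
    a: str
    b: str
    parent: str | None = None
    offspring: str | None = None
    bases: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    suspect: bool = False

    @property
    def basis(self) -> str:
        return self.bases[0] if self.bases else "unoriented"

    @property
    def oriented(self) -> bool:
        return self.parent is not None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))

    def orient(self, parent: str, offspring: str, basis: str) -> None:
        if self.parent is not None and self.parent != parent:
            self.conflicts.append(
                f"{basis} wants {parent} as parent but already oriented "
                f"{self.parent} -> {self.offspring}")
            return
        self.parent, self.offspring = parent, offspring
        if basis not in self.bases:
            self.bases.append(basis)


def _propagate(duos: list[OrientedDuo], known_offspring: dict[str, str],
               basis: str) -> None:
    """Iterate: any known offspring must be the parent in its other duos;
    each new offspring joins the known set.  Runs to a fixed point.

    ``known_offspring`` maps individual -> note on how it became an
    offspring (trio or duo)."""
    changed = True
    while changed:
        changed = False
        for d in duos:
            if d.oriented:
                continue
            a_off = d.a in known_offspring
            b_off = d.b in known_offspring
            if a_off and b_off:
                d.conflicts.append(
                    f"both {d.a} ({known_offspring[d.a]}) and {d.b} "
                    f"({known_offspring[d.b]}) are established offspring; "
                    "duo left unoriented")
                continue
            if a_off:
                d.orient(d.a, d.b, basis)
            elif b_off:
                d.orient(d.b, d.a, basis)
            else:
                continue
            if d.oriented:
                known_offspring.setdefault(
                    d.offspring, f"offspring of {d.parent} by {basis}")
                changed = True


def orient_from_trios(accepted_duos: list[DuoResult],
                      accepted_trios: list[TrioResult]) -> list[OrientedDuo]:
    """First orientation pass.  Duos subsumed by an accepted trio
    (offspring-parent edges of the trio) are dropped; trio offspring seed
    the propagation."""
    trio_edges = set()
    trio_offspring: dict[str, str] = {}
    for t in accepted_trios:
        trio_edges.add(frozenset((t.offspring, t.p1)))
        trio_edges.add(frozenset((t.offspring, t.p2)))
        trio_offspring[t.offspring] = f"offspring in trio ({t.p1} x {t.p2})"
    duos = [OrientedDuo(d.a, d.b) for d in accepted_duos
            if frozenset((d.a, d.b)) not in trio_edges]
    known = dict(trio_offspring)
    # direct trio-membership orientations first, then the cascade
    for d in duos:
        a_off = d.a in trio_offspring
        b_off = d.b in trio_offspring
        if a_off and b_off:
            d.conflicts.append(
                f"both {d.a} and {d.b} are trio offspring; duo unoriented")
        elif a_off:
            d.orient(d.a, d.b, "trio_membership")
            known.setdefault(d.offspring, "oriented via trio membership")
        elif b_off:
            d.orient(d.b, d.a, "trio_membership")
            known.setdefault(d.offspring, "oriented via trio membership")
    _propagate(duos, known, "propagation")
    return duos


def orient_from_metadata(duos: list[OrientedDuo],
                         metadata: dict[str, CultivarMetadata],
                         min_year_gap: int = 10,
                         accepted_trios: list[TrioResult] | None = None
                         ) -> list[OrientedDuo]:
    """Metadata passes over the still-unoriented duos, in place.

    Documented parentage outranks dates: when both rules apply and
    disagree, parentage wins and the disagreement is recorded as a
    conflict.  After both passes the trio-style propagation re-runs.
    Finally, individuals inferred as offspring in two or more
    metadata-oriented duos whose two proposed parents do not form an
    accepted trio with them are marked suspect (kept oriented).
    """
    def name_of(ind: str) -> str:
        m = metadata.get(ind)
        return m.preferred_name if m else ind

    names_to_id = {}
    for ind, m in metadata.items():
        names_to_id[m.preferred_name] = ind
        names_to_id.setdefault(ind, ind)

    known: dict[str, str] = {}
    for d in duos:
        if d.oriented:
            known.setdefault(d.offspring, "previously oriented")

    for d in duos:
        if d.oriented:
            continue
        ma, mb = metadata.get(d.a), metadata.get(d.b)
        parentage = None
        if ma and name_of(d.b) in [p for p in ma.documented_parents if p]:
            parentage = (d.b, d.a)  # b documented as a's parent
        elif mb and name_of(d.a) in [p for p in mb.documented_parents if p]:
            parentage = (d.a, d.b)
        date = None
        if (ma and mb and ma.date is not None and mb.date is not None
                and ma.date_precision == "precise"
                and mb.date_precision == "precise"
                and abs(ma.date - mb.date) >= min_year_gap):
            date = (d.a, d.b) if ma.date < mb.date else (d.b, d.a)
        if parentage:
            d.orient(parentage[0], parentage[1], "documented_parentage")
            if date and date != parentage:
                d.conflicts.append(
                    "documented dates contradict documented parentage; "
                    "parentage retained")
        elif date:
            d.orient(date[0], date[1], "documented_date")
        if d.oriented:
            known.setdefault(d.offspring, f"oriented by {d.basis}")

    _propagate(duos, known, "propagation")

    # cross-check: joint parents of a doubly-inferred offspring should trio
    if accepted_trios is not None:
        trio_parent_pairs = {(t.offspring, frozenset((t.p1, t.p2)))
                             for t in accepted_trios}
        by_offspring: dict[str, list[OrientedDuo]] = {}
        for d in duos:
            if d.oriented and set(d.bases) & {"documented_date",
                                              "documented_parentage"}:
                by_offspring.setdefault(d.offspring, []).append(d)
        for off, ds in by_offspring.items():
            if len(ds) >= 2:
                parents = frozenset(d.parent for d in ds)
                if len(parents) == 2 and (off, parents) not in trio_parent_pairs:
                    for d in ds:
                        d.suspect = True
                        d.conflicts.append(
                            f"{off} inferred as offspring of both "
                            f"{sorted(parents)} but the trio was not accepted")
    return duos


def check_acyclic(duos: list[OrientedDuo],
                  trios: list[TrioResult] | None = None) -> list[str]:
    """Oriented duos plus trios must form a DAG; every directed cycle is
    reported as a conflict (and attached to the member duos), never
    silently broken."""
    g = nx.DiGraph()
    for d in duos:
        if d.oriented:
            g.add_edge(d.parent, d.offspring)
    for t in trios or []:
        g.add_edge(t.p1, t.offspring)
        g.add_edge(t.p2, t.offspring)
    conflicts = []
    try:
        cycles = list(nx.simple_cycles(g))
    except nx.NetworkXNoCycle:  # pragma: no cover
        cycles = []
    for cyc in cycles:
        note = "directed cycle: " + " -> ".join(cyc + [cyc[0]])
        conflicts.append(note)
        cyc_set = set(cyc)
        for d in duos:
            if d.oriented and {d.parent, d.offspring} <= cyc_set:
                d.conflicts.append(note)
                d.suspect = True
    return conflicts


def orientation_report(duos: list[OrientedDuo]) -> dict:
    """Counts per orientation basis plus all recorded conflicts; the
    per-basis counts sum to the total number of duos."""
    counts = {b: 0 for b in BASES}
    conflicts = []
    for d in duos:
        counts[d.basis] += 1
        for c in d.conflicts:
            conflicts.append(f"({d.a},{d.b}): {c}")
    return {"counts": counts, "n_duos": len(duos),
            "n_oriented": sum(1 for d in duos if d.oriented),
            "n_unoriented": sum(1 for d in duos if not d.oriented),
            "n_suspect": sum(1 for d in duos if d.suspect),
            "conflicts": conflicts}


def write_oriented_tsv(duos: list[OrientedDuo], path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\toffspring\tbasis\tsuspect\tconflicts\n")
        for d in duos:
            if d.oriented:
                fh.write(f"{d.parent}\t{d.offspring}\t{d.basis}\t"
                         f"{d.suspect}\t{'; '.join(d.conflicts)}\n")
        for d in duos:
            if not d.oriented:
                fh.write(f"{d.a}|{d.b}\t-\tunoriented\t{d.suspect}\t"
                         f"{'; '.join(d.conflicts)}\n")
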