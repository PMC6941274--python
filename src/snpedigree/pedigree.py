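"""Pedigree assembly and analysis.

Accepted trios contribute two parents, oriented duos one, and each
grandparent group contributes a placeholder node — an ungenotyped
missing parent whose own parents are the inferred grandparent couple and
whose single child is the orphan offspring.  The result is a directed
acyclic graph with parent -> child edges.

Node classes follow the usual germplasm-pedigree convention ("indic"):
1 founder (no known parents), 2 placeholder with both parents known,
3 semi-founder (one parent known), 4 both parents known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .exclusion import DuoResult, GrandparentGroupResult, TrioResult
from .genotype_io import CultivarMetadata
from .orientation import OrientedDuo


class PedigreeBuildError(ValueError):
    pass


PLACEHOLDER_PREFIX = "MISSING_PARENT_OF_"


@dataclass
class Pedigree:
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    placeholders: set[str] = field(default_factory=set)

    # -- structure ----------------------------------------------------------

    def add_parent(self, child: str, parent: str) -> None:
        self.graph.add_node(child)
        self.graph.add_node(parent)
        current = set(self.graph.predecessors(child))
        if parent in current:
            return
        if len(current) >= 2:
            raise PedigreeBuildError(
                f"{child} would get a third parent {parent} "
                f"(already {sorted(current)})")
        self.graph.add_edge(parent, child)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self.graph.predecessors(node)))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self.graph.successors(node)))

    def is_placeholder(self, node: str) -> bool:
        return node in self.placeholders

    def indic(self, node: str) -> int:
        np_ = len(self.parents(node))
        if node in self.placeholders:
            return 2
        if np_ == 0:
            return 1
        if np_ == 1:
            return 3
        return 4

    @property
    def founders(self) -> list[str]:
        return [n for n in self.graph.nodes
                if self.graph.in_degree(n) == 0 and n not in self.placeholders]

    # -- analyses -----------------------------------------------------------

    def generations(self) -> tuple[dict[str, int], int]:
        """Generation depth: 1 for founders, else 1 + max over parents.
        Placeholder nodes count in depth (they sit between the
        grandparent couple and the orphan offspring)."""
        if not nx.is_directed_acyclic_graph(self.graph):
            raise PedigreeBuildError("pedigree contains a directed cycle")
        depth: dict[str, int] = {}
        for node in nx.topological_sort(self.graph):
            preds = list(self.graph.predecessors(node))
            depth[node] = 1 if not preds else 1 + max(depth[p] for p in preds)
        return depth, (max(depth.values()) if depth else 0)

    def descendants(self, node: str, include_placeholders: bool = False
                    ) -> set[str]:
        """Transitive closure of child links.  Descent is followed
        through placeholder nodes, but by default placeholders are not
        counted (only named genotypes are)."""
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        desc = nx.descendants(self.graph, node)
        if not include_placeholders:
            desc -= self.placeholders
        return desc

    def ancestors_inclusive(self, node: str) -> set[str]:
        return {node} | nx.ancestors(self.graph, node)

    def inbred_nodes(self) -> list[tuple[str, set[str]]]:
        """Nodes with two parents whose inclusive ancestor sets intersect.
        Each parent counts as its own ancestor, so a parent that is also
        a grandparent (recurrent parent) triggers inbreeding."""
        out = []
        for node in self.graph.nodes:
            ps = self.parents(node)
            if len(ps) != 2:
                continue
            shared = (self.ancestors_inclusive(ps[0])
                      & self.ancestors_inclusive(ps[1]))
            if shared:
                out.append((node, shared))
        return out

    def stats(self) -> dict:
        depth, max_depth = self.generations()
        inbred = self.inbred_nodes()
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_placeholders": len(self.placeholders),
            "n_founders": len(self.founders),
            "max_generations": max_depth,
            "n_inbred": len(inbred),
            "inbred_nodes": sorted(n for n, _ in inbred),
            "indic_counts": {
                k: sum(1 for n in self.graph.nodes if self.indic(n) == k)
                for k in (1, 2, 3, 4)},
        }


def build_pedigree(trios: list[TrioResult],
                   oriented_duos: list[OrientedDuo],
                   gp_groups: list[GrandparentGroupResult] | None = None,
                   exclude: set[str] | None = None) -> Pedigree:
    """Assemble the pedigree.  Unoriented duos are left out; excluded ids
    (e.g. mapping-population progenies) are dropped with their
    relationships.  Contradictory parent assignments (a third distinct
    parent for any node) raise :class:`PedigreeBuildError` naming the
    node."""
    exclude = exclude or set()
    ped = Pedigree()
    errors = []
    for t in trios:
        if {t.offspring, t.p1, t.p2} & exclude:
            continue
        for p in (t.p1, t.p2):
            try:
                ped.add_parent(t.offspring, p)
            except PedigreeBuildError as e:
                errors.append(str(e))
    for d in oriented_duos:
        if not d.oriented or {d.parent, d.offspring} & exclude:
            continue
        try:
            ped.add_parent(d.offspring, d.parent)
        except PedigreeBuildError as e:
            errors.append(str(e))
    for g in gp_groups or []:
        if {g.offspring, g.parent, g.gp1, g.gp2} & exclude:
            continue
        ph = PLACEHOLDER_PREFIX + g.offspring
        ped.placeholders.add(ph)
        try:
            ped.add_parent(g.offspring, g.parent)
            ped.add_parent(g.offspring, ph)
            ped.add_parent(ph, g.gp1)
            ped.add_parent(ph, g.gp2)
        except PedigreeBuildError as e:
            errors.append(str(e))
    if errors:
        raise PedigreeBuildError("contradictory parent assignments:\n  "
                                 + "\n  ".join(errors))
    if not nx.is_directed_acyclic_graph(ped.graph):
        cyc = nx.find_cycle(ped.graph)
        raise PedigreeBuildError(f"pedigree contains a cycle: {cyc}")
    return ped


# ---------------------------------------------------------------------------
# Duo network
# ---------------------------------------------------------------------------

def duo_network_components(accepted_duos: list[DuoResult],
                           exclude: set[str] | None = None) -> dict:
    """Connected components and degree histogram of the undirected
    first-degree-relationship network."""
    exclude = exclude or set()
    g = nx.Graph()
    for d in accepted_duos:
        if {d.a, d.b} & exclude:
            continue
        g.add_edge(d.a, d.b)
    comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    degree = dict(g.degree())
    degree_bins = {"1": 0, "2": 0, "3-5": 0, "6-10": 0, ">10": 0}
    for _, k in degree.items():
        if k == 1:
            degree_bins["1"] += 1
        elif k == 2:
            degree_bins["2"] += 1
        elif k <= 5:
            degree_bins["3-5"] += 1
        elif k <= 10:
            degree_bins["6-10"] += 1
        else:
            degree_bins[">10"] += 1
    return {"component_sizes": comps, "n_components": len(comps),
            "n_individuals": g.number_of_nodes(), "degree": degree,
            "degree_bins": degree_bins}


# ---------------------------------------------------------------------------
# Chronology
# ---------------------------------------------------------------------------

def chronology_check(pedigree: Pedigree,
                     metadata: dict[str, CultivarMetadata]) -> pd.DataFrame:
    """Per parent-child edge: consistent (parent strictly older),
    inconsistent (parent dated same year or later), or unassessable
    (either date missing or not precise)."""
    rows = []
    for parent, child in pedigree.graph.edges:
        mp, mc = metadata.get(parent), metadata.get(child)
        if (mp is None or mc is None or mp.date is None or mc.date is None
                or mp.date_precision != "precise"
                or mc.date_precision != "precise"):
            status = "unassessable"
        elif mp.date >= mc.date:
            status = "inconsistent"
        else:
            status = "consistent"
        rows.append({"parent": parent, "child": child,
                     "parent_date": mp.date if mp else None,
                     "child_date": mc.date if mc else None,
                     "status": status})
    return pd.DataFrame(rows, columns=["parent", "child", "parent_date",
                                       "child_date", "status"])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: Pedigree, path, format: str = "csv") -> None:
    """``csv``: id,parent1,parent2 (empty = unknown).  ``pedimap``: a
    Pedimap-style text table NAME, PARENT1, PARENT2, indic with the
    legend 1 founder / 2 placeholder with both parents known /
    3 semi-founder / 4 both parents known."""
    rows = []
    for node in sorted(pedigree.graph.nodes):
        ps = list(pedigree.parents(node)) + ["", ""]
        rows.append((node, ps[0], ps[1], pedigree.indic(node)))
    with open(path, "w") as fh:
        if format == "csv":
            fh.write("id,parent1,parent2\n")
            for name, p1, p2, _ in rows:
                fh.write(f"{name},{p1},{p2}\n")
        elif format == "pedimap":
            fh.write("NAME\tPARENT1\tPARENT2\tindic\n")
            for name, p1, p2, ind in rows:
                fh.write(f"{name}\t{p1 or 'NA'}\t{p2 or 'NA'}\t{ind}\n")
        else:
            raise ValueError(f"unknown pedigree format {format!r}")


def read_pedigree(path) -> Pedigree:
    """Read the 3-column CSV form back; placeholder nodes are recognised
    by their synthetic id prefix."""
    df = pd.read_csv(path, dtype=str).fillna("")
    ped = Pedigree()
    for _, r in df.iterrows():
        ped.graph.add_node(r["id"])
        if r["id"].startswith(PLACEHOLDER_PREFIX):
            ped.placeholders.add(r["id"])
        for col in ("parent1", "parent2"):
            if r[col]:
                ped.add_parent(r["id"], r[col])
                if r[col].startswith(PLACEHOLDER_PREFIX):
                    ped.placeholders.add(r[col])
    return ped
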