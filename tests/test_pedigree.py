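"""Pedigree assembly, generations, descendants, inbreeding, network."""

import networkx as nx
import numpy as np
import pytest

import snpedigree as sp
from snpedigree.exclusion import DuoResult, GrandparentGroupResult, TrioResult
from snpedigree.genotype_io import CultivarMetadata
from snpedigree.orientation import OrientedDuo
from snpedigree.pedigree import (Pedigree, PedigreeBuildError, build_pedigree,
                                 chronology_check, duo_network_components,
                                 read_pedigree, write_pedigree)


def trio(o, p1, p2):
    return TrioResult(o, p1, p2, 0, 100, accepted=True)


def odou(parent, offspring):
    d = OrientedDuo(parent, offspring)
    d.orient(parent, offspring, "documented_date")
    return d


def gpg(o, p, g1, g2):
    return GrandparentGroupResult(o, p, g1, g2, 0, 0, accepted=True)


def test_build_constructive_example():
    ped = build_pedigree([trio("C", "A", "B")], [odou("C", "D")],
                         [gpg("E", "D", "F", "G")])
    assert ped.graph.number_of_nodes() == 8  # 7 named + 1 placeholder
    assert len(ped.placeholders) == 1
    ph = next(iter(ped.placeholders))
    assert set(ped.parents("E")) == {"D", ph}
    assert set(ped.parents(ph)) == {"F", "G"}
    assert ped.indic(ph) == 2
    assert ped.indic("A") == 1 and ped.indic("C") == 4 and ped.indic("D") == 3


def test_build_empty_and_contradiction():
    assert build_pedigree([], [], []).graph.number_of_nodes() == 0
    with pytest.raises(PedigreeBuildError, match="C"):
        build_pedigree([trio("C", "A", "B")], [odou("X", "C")], [])


def test_generations_depths():
    ped = build_pedigree([], [], [])
    ped.graph.add_nodes_from("AB")
    depth, mx = ped.generations()
    assert mx == 1 and depth == {"A": 1, "B": 1}
    chain = build_pedigree([], [odou(f"N{i}", f"N{i+1}") for i in range(6)],
                           [])
    _, mx = chain.generations()
    assert mx == 7
    # depth is max over parents
    ped2 = build_pedigree([trio("C", "A", "B")], [odou("X", "B")], [])
    depth2, _ = ped2.generations()
    assert depth2["C"] == 3  # through B (depth 2), not A (depth 1)


def test_cycle_detected():
    ped = Pedigree()
    ped.graph.add_edges_from([("A", "B"), ("B", "A")])
    with pytest.raises(PedigreeBuildError, match="cycle"):
        ped.generations()


def test_descendants_against_dfs_oracle():
    rng = np.random.default_rng(17)
    for _ in range(5):
        ped = Pedigree()
        nodes = [f"N{i}" for i in range(200)]
        for k, n in enumerate(nodes):
            ped.graph.add_node(n)
            if k >= 2:
                for p in rng.choice(k, size=rng.integers(0, 3),
                                    replace=False):
                    ped.add_parent(n, nodes[p])
        for start in rng.choice(200, size=10, replace=False):
            node = nodes[start]
            oracle, stack = set(), [node]
            while stack:
                x = stack.pop()
                for c in ped.graph.successors(x):
                    if c not in oracle:
                        oracle.add(c)
                        stack.append(c)
            assert ped.descendants(node, include_placeholders=True) == oracle
        leaf = [n for n in nodes if ped.graph.out_degree(n) == 0][0]
        assert ped.descendants(leaf) == set()
    with pytest.raises(KeyError):
        ped.descendants("nope")


def test_descent_through_placeholders_counts_named_nodes_only():
    ped = build_pedigree([], [], [gpg("O", "P", "G1", "G2")])
    ph = next(iter(ped.placeholders))
    assert ped.descendants("G1") == {"O"}
    assert ped.descendants("G1", include_placeholders=True) == {ph, "O"}


def test_inbreeding_detection():
    # parents are full sibs -> shared grandparents
    ped = build_pedigree([trio("P1", "G1", "G2"), trio("P2", "G1", "G2"),
                          trio("X", "P1", "P2")], [], [])
    inbred = dict(ped.inbred_nodes())
    assert "X" in inbred and {"G1", "G2"} <= inbred["X"]
    # recurrent parent: A is both parent and grandparent of X
    ped2 = build_pedigree([trio("B", "A", "C"), trio("X", "A", "B")], [], [])
    inbred2 = dict(ped2.inbred_nodes())
    assert "X" in inbred2 and "A" in inbred2["X"]
    # two founder parents -> not inbred
    ped3 = build_pedigree([trio("X", "A", "B")], [], [])
    assert ped3.inbred_nodes() == []


def test_stats_and_indic_partition():
    ped = build_pedigree([trio("C", "A", "B")], [odou("C", "D")],
                         [gpg("E", "D", "F", "G")])
    st = ped.stats()
    assert sum(st["indic_counts"].values()) == st["n_nodes"]
    assert st["n_founders"] == len([n for n in ped.graph.nodes
                                    if ped.graph.in_degree(n) == 0
                                    and not ped.is_placeholder(n)])


def test_duo_network_components_and_degrees():
    duos = [DuoResult("A", "B", 0, 10, {}), DuoResult("C", "D", 0, 10, {})]
    net = duo_network_components(duos)
    assert net["component_sizes"] == [2, 2]
    star = [DuoResult("HUB", f"K{i}", 0, 10, {}) for i in range(5)]
    net2 = duo_network_components(star)
    assert net2["component_sizes"] == [6]
    assert net2["degree"]["HUB"] == 5
    assert net2["degree_bins"]["3-5"] == 1 and net2["degree_bins"]["1"] == 5


def test_chronology_check_statuses():
    ped = build_pedigree([], [odou("P", "C"), odou("Q", "D"),
                              odou("R", "E")], [])
    def md(n, yr, prec="precise"):
        return CultivarMetadata(n, n, date=yr, date_precision=prec)

    meta = {"P": md("P", 1800), "C": md("C", 1900), "Q": md("Q", 1900),
            "D": md("D", 1800), "R": md("R", 1700, "approximate"),
            "E": md("E", 1800)}
    rep = chronology_check(ped, meta)
    status = dict(zip(zip(rep.parent, rep.child), rep.status))
    assert status[("P", "C")] == "consistent"
    assert status[("Q", "D")] == "inconsistent"
    assert status[("R", "E")] == "unassessable"


def test_planted_wrong_dates_are_the_flagged_edges():
    """On the truth pedigree, chronology inconsistencies are exactly the
    edges whose child carries a planted wrong date (wrong dates are
    planted older than the founder era)."""
    cfg = sp.SimulationConfig(n_founders=30, n_generations=3,
                              offspring_per_generation=30, n_snps=50,
                              date_missing_rate=0.1, date_wrong_rate=0.15,
                              date_approximate_rate=0.0, seed=91)
    matrix, meta, truth = sp.simulate(cfg)
    ped = Pedigree()
    for child, parents in truth.pedigree.items():
        for p in parents:
            ped.add_parent(child, p)
    rep = chronology_check(ped, meta)
    bad = rep[rep.status == "inconsistent"]
    assert len(bad) > 0
    assert set(bad.child) <= truth.wrong_date_ids
    # and every assessable edge into a wrong-dated child is flagged
    assessable = rep[(rep.status != "unassessable")]
    for _, row in assessable.iterrows():
        if row.child in truth.wrong_date_ids:
            assert row.status == "inconsistent"
    # clean metadata -> no flags
    clean = {k: CultivarMetadata(k, k, date=truth.true_dates[k],
                                 date_precision="precise")
             for k in truth.true_dates}
    assert (chronology_check(ped, clean).status != "inconsistent").all()


def test_write_read_round_trip(tmp_path):
    ped = build_pedigree([trio("C", "A", "B")], [odou("C", "D")],
                         [gpg("E", "D", "F", "G")])
    path = tmp_path / "ped.csv"
    write_pedigree(ped, path, "csv")
    again = read_pedigree(path)
    assert set(again.graph.nodes) == set(ped.graph.nodes)
    assert set(again.graph.edges) == set(ped.graph.edges)
    assert again.placeholders == ped.placeholders

    pm = tmp_path / "ped.txt"
    write_pedigree(ped, pm, "pedimap")
    lines = pm.read_text().splitlines()
    assert lines[0].split("\t") == ["NAME", "PARENT1", "PARENT2", "indic"]
    rows = {l.split("\t")[0]: l.split("\t") for l in lines[1:]}
    assert rows["A"][1:] == ["NA", "NA", "1"]       # founder
    ph = next(iter(ped.placeholders))
    assert rows[ph][3] == "2" and "NA" not in rows[ph][1:3]  # placeholder


def test_rebuilt_pedigree_equals_truth_on_clean_run(clean_cohort):
    """A clean cohort with every ancestor genotyped reconstructs the
    diploid truth pedigree exactly: node-for-node, edge-for-edge, no
    placeholders."""
    matrix, meta, truth = clean_cohort
    thr = sp.ThresholdConfig.for_error_rate(0.0)
    run = sp.run_all(matrix, meta, sp.PipelineConfig(thresholds=thr, seed=101))
    ped = run.pedigree
    assert ped.placeholders == set()
    truth_edges = {(p, c) for c, ps in truth.pedigree.items() for p in ps
                   if matrix.is_diploid(c)}
    assert set(ped.graph.edges) == truth_edges
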