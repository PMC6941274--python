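"""Mendelian-error counting and thresholding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpedigree as sp
from snpedigree.exclusion import (DuoResult, ThresholdConfig, classify_duos,
                                  classify_trios, duo_me,
                                  enumerate_candidate_trios, grandparent_me,
                                  grandparent_search, me_histogram,
                                  per_chromosome_me_report, trio_me)
from .conftest import make_matrix


# ---------------------------------------------------------------------------
# duo ME
# ---------------------------------------------------------------------------

def test_duo_me_counts_opposing_homozygotes():
    m = make_matrix([[0, 1, 2], [2, 0, 2]], ids=["a", "b"])
    r = duo_me(m, "a", "b")
    assert r.me_count == 1  # only SNP0; het-vs-hom is consistent
    assert r.n_informative == 3


def test_duo_me_identical_genotypes_zero():
    m = make_matrix([[0, 1, 2, 1], [0, 1, 2, 1]], ids=["a", "b"])
    assert duo_me(m, "a", "b").me_count == 0


def test_duo_me_skips_missing_calls():
    m = make_matrix([[0, -1, 2], [2, 2, -1]], ids=["a", "b"])
    r = duo_me(m, "a", "b")
    assert r.me_count == 1 and r.n_informative == 1


@given(st.integers(0, 2 ** 31 - 1))
@settings(deadline=None, max_examples=10, derandomize=True)
def test_duo_me_symmetric(seed):
    rng = np.random.default_rng(seed)
    m = make_matrix(rng.integers(-1, 3, size=(2, 50)), ids=["a", "b"])
    try:
        assert duo_me(m, "a", "b").me_count == duo_me(m, "b", "a").me_count
    except sp.exclusion.InsufficientDataError:
        pass


def test_unrelated_duo_me_matches_analytic_expectation():
    """Unrelated HWE pair at MAF 0.5: E[ME] = 2 p^2 q^2 N = 125 at N=1000."""
    cfg = sp.SimulationConfig(n_founders=40, n_generations=1, n_snps=1000,
                              maf_range=(0.5, 0.5), error_rate=0,
                              missing_rate=0, seed=21)
    matrix, _, _ = sp.simulate(cfg)
    ids = matrix.individuals
    mes = [duo_me(matrix, a, b).me_count
           for a, b in itertools.combinations(ids[:20], 2)]
    expected = 2 * 0.5 ** 4 * 1000
    se = np.sqrt(expected * (1 - 2 * 0.5 ** 4))
    assert abs(np.mean(mes) - expected) < 3 * se / np.sqrt(len(mes))


def test_per_chromosome_breakdown_sums_to_total(noisy_cohort):
    matrix, _, truth = noisy_cohort
    child, parents = next(iter(truth.pedigree.items()))
    r = duo_me(matrix, child, parents[0])
    assert sum(r.per_chromosome_me.values()) == r.me_count


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_classification_is_strict_less_than():
    cfg = ThresholdConfig()
    duos = [DuoResult("a", "b", 599, 253_095, {}),
            DuoResult("c", "d", 600, 253_095, {})]
    accepted, thr = classify_duos(duos, cfg, 253_095)
    assert thr == 600
    assert [d.accepted for d in duos] == [True, False]


def test_threshold_rates_reproduce_reference_absolute_counts():
    cfg = ThresholdConfig()
    assert ThresholdConfig.absolute(cfg.duo_me_rate, 253_095) == 600
    assert ThresholdConfig.absolute(cfg.duo_first_pass_rate, 275_223) == 1000
    assert ThresholdConfig.absolute(cfg.gp_stage1_rate, 25_310) == 100
    assert ThresholdConfig.absolute(cfg.gp_stage2_rate, 253_095) == 100
    # arithmetic scaling to a small panel
    assert ThresholdConfig.absolute(cfg.duo_me_rate, 5_000) == 12


def test_error_matched_thresholds_sit_in_the_me_gap(noisy_cohort):
    """With per-call error 0.002, thresholds derived from the error model
    separate true duos (error-driven ME) from the nearest competing
    relationship."""
    matrix, _, truth = noisy_cohort
    thr = ThresholdConfig.for_error_rate(0.002)
    abs_thr = ThresholdConfig.absolute(thr.duo_me_rate, matrix.n_snps)
    present = set(matrix.individuals)
    true_me = [duo_me(matrix, *sorted(p)).me_count
               for p in truth.true_duos() if p <= present][:100]
    assert max(true_me) < abs_thr
    hs = [p for p in truth.half_sib_pairs() if p <= present][:30]
    hs_me = [duo_me(matrix, *sorted(p)).me_count for p in hs]
    assert min(hs_me) > abs_thr


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def test_enumerate_candidate_trios():
    duos = [DuoResult("X", "A", 0, 10, {}), DuoResult("X", "B", 0, 10, {}),
            DuoResult("C", "X", 0, 10, {}), DuoResult("Y", "A", 0, 10, {})]
    cands = enumerate_candidate_trios(duos)
    assert ("X", "A", "B") in cands and ("X", "A", "C") in cands \
        and ("X", "B", "C") in cands
    assert all(o != "Y" for o, _, _ in cands)  # single duo -> no candidates
    assert len(cands) == len(set(cands))


def test_trio_me_examples():
    m = make_matrix([[1], [0], [0]], ids=["O", "P1", "P2"])
    assert trio_me(m, "O", "P1", "P2").me_count == 1
    m2 = make_matrix([[1], [0], [2]], ids=["O", "P1", "P2"])
    assert trio_me(m2, "O", "P1", "P2").me_count == 0


def _gamete_compatible(o, p1, p2):
    """Oracle: does any pair of gametes from p1 and p2 produce o?"""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return any(sorted((a, b)) == list(alleles[o])
               for a in alleles[p1] for b in alleles[p2])


def test_trio_me_rule_equals_gamete_oracle_on_all_27_configurations():
    for o, p1, p2 in itertools.product((0, 1, 2), repeat=3):
        m = make_matrix([[o], [p1], [p2]], ids=["O", "P1", "P2"])
        flagged = trio_me(m, "O", "P1", "P2").me_count == 1
        assert flagged == (not _gamete_compatible(o, p1, p2)), (o, p1, p2)


@given(st.integers(0, 2 ** 31 - 1))
@settings(deadline=None, max_examples=10, derandomize=True)
def test_trio_me_symmetric_in_parents_and_bounds_duo(seed):
    rng = np.random.default_rng(seed)
    m = make_matrix(rng.integers(-1, 3, size=(3, 60)), ids=["O", "P", "Q"])
    try:
        t = trio_me(m, "O", "P", "Q")
        assert t.me_count == trio_me(m, "O", "Q", "P").me_count
        # trio conditions are a per-SNP superset of each duo's opposing
        # homozygotes (restricted to the trio-informative SNPs)
        go, gp, gq = m.calls[0], m.calls[1], m.calls[2]
        inf = (go >= 0) & (gp >= 0) & (gq >= 0)
        for g in (gp, gq):
            opp = (((go == 0) & (g == 2)) | ((go == 2) & (g == 0))) & inf
            assert t.me_count >= int(opp.sum())
    except sp.exclusion.InsufficientDataError:
        pass


def test_true_trios_accepted_false_candidates_rejected(noisy_run, noisy_cohort):
    """Study conditions: every true trio accepted, every false candidate
    (parent+grandparent or parent+sib pairings) rejected."""
    matrix, _, truth = noisy_cohort
    accepted = {(t.offspring, frozenset((t.p1, t.p2))) for t in noisy_run.trios}
    truth_trios = truth.true_trios()
    present = set(matrix.diploid_ids())
    expected = {(c, ps) for c, ps in truth_trios
                if c in present and set(ps) <= present}
    assert accepted == expected


# ---------------------------------------------------------------------------
# grandparent groups
# ---------------------------------------------------------------------------

def test_grandparent_me_rules():
    # GP couple hom-ref, offspring hom-alt -> ME regardless of parent
    m = make_matrix([[2], [1], [0], [0]], ids=["O", "P", "G1", "G2"])
    assert grandparent_me(m, "O", "P", "G1", "G2") == 1
    # offspring het with accepted parent hom for the same allele -> ME
    m = make_matrix([[1], [0], [0], [0]], ids=["O", "P", "G1", "G2"])
    assert grandparent_me(m, "O", "P", "G1", "G2") == 1
    # het offspring whose het comes through the accepted parent -> fine
    m = make_matrix([[1], [2], [0], [0]], ids=["O", "P", "G1", "G2"])
    assert grandparent_me(m, "O", "P", "G1", "G2") == 0
    # grandparents not homozygous for the same allele -> never ME
    m = make_matrix([[2], [0], [0], [2]], ids=["O", "P", "G1", "G2"])
    assert grandparent_me(m, "O", "P", "G1", "G2") == 0


def test_grandparent_me_skips_missing():
    m = make_matrix([[2, 2], [-1, 1], [0, 0], [0, 0]],
                    ids=["O", "P", "G1", "G2"])
    assert grandparent_me(m, "O", "P", "G1", "G2") == 1


def test_masked_parent_grandparent_recovery(masked_parent_setup):
    """Deleting a genotyped parent: the search recovers exactly its
    parent couple for the orphaned duos, and never the accepted parent's
    own parents (wrong side)."""
    matrix, meta, truth, target = masked_parent_setup
    thr = sp.ThresholdConfig.for_error_rate(0.002)
    run = sp.run_all(matrix, meta, sp.PipelineConfig(thresholds=thr, seed=11))
    true_couple = frozenset(truth.pedigree[target])
    # recoverable orphans: the other parent must be distinct from the
    # grandparent couple (a parent x grandparent cross leaves only three
    # distinct roles, outside the scope of the four-individual test)
    orphan_children = {c for c, ps in truth.pedigree.items()
                       if target in ps and c in matrix.individuals
                       and matrix.is_diploid(c)
                       and not (set(ps) - {target}) & true_couple}
    recovered = {g.offspring: frozenset((g.gp1, g.gp2))
                 for g in run.gp_groups}
    for child in orphan_children:
        assert recovered.get(child) == true_couple
    for g in run.gp_groups:
        parent_parents = truth.pedigree.get(g.parent)
        if parent_parents:
            assert frozenset((g.gp1, g.gp2)) != frozenset(parent_parents)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_per_chromosome_report_flags_concentrated_errors():
    per_chrom = {9: 191}
    per_chrom.update({c: 1 for c in range(1, 30) if c != 9 and c <= 17})
    per_chrom[10] += 13  # total 220, chr9 has 191
    d = DuoResult("H31", "Baujade", 220, 100_000, per_chrom)
    uniform = DuoResult("u", "v", 17, 100_000,
                        {c: 1 for c in range(1, 18)})
    rep = per_chromosome_me_report([d, uniform])
    row = rep[rep.a == "H31"].iloc[0]
    assert bool(row.flagged) and row.max_chrom == 9
    assert row.max_fraction == pytest.approx(191 / 220)
    assert not rep[rep.a == "u"].iloc[0].flagged


def test_null_allele_segment_is_flagged_with_planted_chromosome():
    cfg = sp.SimulationConfig(n_founders=20, n_generations=3,
                              offspring_per_generation=25, n_snps=3000,
                              error_rate=0.0, missing_rate=0.0,
                              null_allele=sp.NullAlleleSpec(
                                  chromosome=13, n_affected=3),
                              seed=77)
    matrix, _, truth = sp.simulate(cfg)
    results = []
    for child, parents in truth.pedigree.items():
        for p in parents:
            results.append(duo_me(matrix, child, p))
    rep = per_chromosome_me_report(results, min_me=5)
    flagged = rep[rep.flagged]
    assert len(flagged) > 0
    assert set(flagged.max_chrom) == {13}
    affected = set(truth.null_allele_affected)
    for _, row in flagged.iterrows():
        assert {row.a, row.b} & affected


def test_me_histogram_reports_largest_gap():
    df = me_histogram([0, 2, 3, 500, 510, 900])
    assert df.attrs["largest_gap"] == (3, 500)


def test_zero_error_cohort_has_zero_me_everywhere(clean_cohort):
    matrix, _, truth = clean_cohort
    present = set(matrix.individuals)
    for child, parents in truth.pedigree.items():
        if child not in present:
            continue
        for p in parents:
            assert duo_me(matrix, child, p).me_count == 0
        if matrix.is_diploid(child):
            assert trio_me(matrix, child, *parents).me_count == 0
    # grandparent groups on the truth pedigree
    checked = 0
    for child, parents in truth.pedigree.items():
        if not matrix.is_diploid(child):
            continue
        for p in parents:
            other = parents[0] if p == parents[1] else parents[1]
            gps = truth.pedigree.get(other)
            if gps and len({child, p, *gps}) == 4:
                assert grandparent_me(matrix, child, p, *gps) == 0
                checked += 1
    assert checked > 0
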