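"""Parentage tests for triploid individuals.

A triploid arises from an unreduced (2n) gamete of one parent plus a
normal haploid (n) gamete of the other.  Triploid calls are recoded to a
pseudo-diploid track (dosage 0 -> homozygous reference, 3 -> homozygous
alternate, 1 and 2 -> heterozygous) and screened with the same
opposing-homozygote duo test as diploids.  The two parents are then told
apart by the tri-hom/di-het count — SNPs homozygous in the recoded
triploid but heterozygous in the candidate parent.  The 2n-gamete parent
transmits both of its alleles, so its heterozygous SNPs can essentially
never appear homozygous in the triploid (barring reassortment through
crossovers in FDR/SDR 2n-gametes and genotyping error); the n-gamete
parent shows a large count.

Diploids that look like offspring of the triploid are finally challenged
with a transmission test: wherever the triploid is heterozygous and its
2n-gamete parent homozygous, the triploid's third allele came from the
n-gamete parent, and a true offspring of the triploid has roughly one
chance in three of receiving it; a diploid that never shows that allele
is an offspring of the 2n-gamete parent (grandparent side), not of the
triploid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import genotype_io as gio
from .exclusion import ThresholdConfig, TrioResult, trio_me


def recode_triploid(raw_calls: np.ndarray,
                    assume_raw: bool | None = None) -> np.ndarray:
    """Pseudo-diploid recoding of raw triploid dosages: 0 -> 0 (hom ref),
    1 and 2 -> 1 (het, AAB/ABB), 3 -> 2 (hom alt); missing preserved.

    Raw and recoded tracks overlap numerically (a raw 2 is a
    heterozygote, a recoded 2 a homozygote), so by default a track is
    taken as raw when it contains a dosage of 3 and as already recoded
    otherwise — which makes the function idempotent.  Pass
    ``assume_raw=True`` for a raw track that happens to contain no
    triple-dose call (the matrix constructor always does).
    """
    raw = np.asarray(raw_calls, dtype=np.int8)
    if raw.size and (raw.max(initial=0) > 3 or raw.min(initial=0) < -1):
        raise gio.ValidationError("triploid dosage outside {0,1,2,3}")
    if assume_raw is None:
        assume_raw = bool((raw == 3).any())
    if not assume_raw:
        return raw.copy()
    out = raw.copy()
    out[(raw == 1) | (raw == 2)] = 1
    out[raw == 3] = 2
    return out


@dataclass
class TriploidResult:
    triploid: str
    candidate: str
    me_count: int
    tri_hom_di_het: int
    inferred_role: str  # 2n_gamete_parent | n_gamete_parent | sib_or_unresolved | rejected


@dataclass
class TriploidExclusionReport:
    triploid: str
    p2n: str
    candidate: str
    count_i: int   # candidate compatible with transmission from the 2n parent
    count_ii: int  # candidate carries the n-gamete-derived allele
    verdict: str   # triploid_excluded_as_parent | unresolved


def tri_hom_di_het_count(matrix: gio.GenotypeMatrix, triploid: str,
                         diploid: str,
                         snp_indices: np.ndarray | None = None) -> int:
    """SNPs homozygous in the (pseudo-diploid) triploid and heterozygous
    in the candidate diploid parent."""
    gt = matrix.calls[matrix.row(triploid)]
    gd = matrix.calls[matrix.row(diploid)]
    if snp_indices is not None:
        gt, gd = gt[snp_indices], gd[snp_indices]
    return int((((gt == 0) | (gt == 2)) & (gd == 1)).sum())


def triploid_duo_scan(matrix: gio.GenotypeMatrix, triploid: str,
                      diploids: list[str] | None = None,
                      config: ThresholdConfig | None = None,
                      snp_indices: np.ndarray | None = None
                      ) -> list[TriploidResult]:
    """Exhaustive duo screen of one triploid against diploid candidates.

    Pairs with duo ME below round(triploid_duo_rate x panel) are retained
    and classified by their tri-hom/di-het count: below
    round(tri_hom_di_het_rate x panel) marks a 2n-gamete parent
    candidate, above it an n-gamete parent (or sib — the duo test cannot
    separate those without the second parent).
    """
    config = config or ThresholdConfig()
    if diploids is None:
        diploids = matrix.diploid_ids()
    n = matrix.n_snps if snp_indices is None else len(snp_indices)
    me_thr = ThresholdConfig.absolute(config.triploid_duo_rate, n)
    hh_thr = ThresholdConfig.absolute(config.tri_hom_di_het_rate, n)
    gt = matrix.calls[matrix.row(triploid)]
    if snp_indices is not None:
        gt = gt[snp_indices]
    out = []
    for d in diploids:
        gd = matrix.calls[matrix.row(d)]
        if snp_indices is not None:
            gd = gd[snp_indices]
        me = int((((gt == 0) & (gd == 2)) | ((gt == 2) & (gd == 0))).sum())
        hh = int((((gt == 0) | (gt == 2)) & (gd == 1)).sum())
        if me >= me_thr:
            role = "rejected"
        elif hh < hh_thr:
            role = "2n_gamete_parent"
        else:
            # the duo test alone cannot separate the n-gamete parent from
            # a sib or other close relative; the trio and transmission
            # tests refine this (see analyze_triploid)
            role = "n_gamete_parent"
        out.append(TriploidResult(triploid, d, me, hh, role))
    return out


def triploid_trio_me(matrix: gio.GenotypeMatrix, triploid: str, p2n: str,
                     pn: str, snp_indices: np.ndarray | None = None,
                     config: ThresholdConfig | None = None) -> TrioResult:
    """Trio ME on the pseudo-diploid track with the standard trio rule;
    accepted below round(triploid_trio_rate x panel)."""
    config = config or ThresholdConfig()
    res = trio_me(matrix, triploid, p2n, pn, snp_indices)
    n = matrix.n_snps if snp_indices is None else len(snp_indices)
    res.accepted = res.me_count < ThresholdConfig.absolute(
        config.triploid_trio_rate, n)
    return res


def default_max_transmission(panel_size: int) -> int:
    """Ceiling on count_ii below which the triploid is excluded as a
    parent; floor of 25 keeps small synthetic panels from degenerating
    to zero tolerance."""
    return max(25, round(1e-4 * panel_size))


def triploid_parent_exclusion(matrix: gio.GenotypeMatrix, triploid: str,
                              p2n: str, candidate: str,
                              snp_indices: np.ndarray | None = None,
                              max_transmission: int | None = None
                              ) -> TriploidExclusionReport:
    """Test whether a low-ME diploid 'offspring' of the triploid is in
    fact an offspring of the triploid's 2n-gamete parent.

    At SNPs where the triploid is heterozygous and the 2n parent
    homozygous, the allele the 2n parent cannot supply came through the
    n gamete.  count_ii tallies candidates homozygous for that allele;
    (almost) none means the triploid passed no n-gamete-derived alleles
    on, so it is excluded as the candidate's parent.
    """
    gt = matrix.calls[matrix.row(triploid)]
    gg = matrix.calls[matrix.row(p2n)]
    gc = matrix.calls[matrix.row(candidate)]
    if snp_indices is not None:
        gt, gg, gc = gt[snp_indices], gg[snp_indices], gc[snp_indices]
    n = len(gt)
    if max_transmission is None:
        max_transmission = default_max_transmission(n)
    informative = (gt == 1) & ((gg == 0) | (gg == 2)) & (gc >= 0)
    if not informative.any():
        return TriploidExclusionReport(triploid, p2n, candidate, 0, 0,
                                       "unresolved")
    # allele the 2n parent is homozygous for: dosage gg; alternative: 2-gg
    other_hom = 2 - gg  # dosage of the genotype homozygous for the other allele
    count_ii = int((informative & (gc == other_hom)).sum())
    count_i = int(informative.sum()) - count_ii
    verdict = ("triploid_excluded_as_parent" if count_ii <= max_transmission
               else "unresolved")
    return TriploidExclusionReport(triploid, p2n, candidate, count_i,
                                   count_ii, verdict)


def analyze_triploid(matrix: gio.GenotypeMatrix, triploid: str,
                     config: ThresholdConfig | None = None,
                     exclude: set[str] | None = None) -> dict:
    """Full per-triploid workflow: exhaustive duo scan, 2n/n-gamete parent
    classification, trio test for every (2n, n) candidate pairing, and
    exclusion reports for the remaining low-ME diploids."""
    config = config or ThresholdConfig()
    exclude = exclude or set()
    diploids = [d for d in matrix.diploid_ids() if d not in exclude]
    scan = triploid_duo_scan(matrix, triploid, diploids, config)
    retained = [r for r in scan if r.inferred_role != "rejected"]
    p2n_cands = [r.candidate for r in retained
                 if r.inferred_role == "2n_gamete_parent"]
    others = [r.candidate for r in retained
              if r.inferred_role == "n_gamete_parent"]
    trios = []
    for p2n, pn in itertools.product(p2n_cands, others):
        trios.append(triploid_trio_me(matrix, triploid, p2n, pn,
                                      config=config))
    accepted_trios = [t for t in trios if t.accepted]
    exclusions = []
    for p2n in p2n_cands:
        for cand in others:
            exclusions.append(
                triploid_parent_exclusion(matrix, triploid, p2n, cand))
    # refine roles: a low-ME/high-tri-hom-di-het candidate is confirmed as
    # the n-gamete parent only through an accepted trio; the others are
    # sibs or otherwise unresolved relatives (the transmission-test
    # verdicts say which of them are offspring of the 2n parent)
    confirmed_n = {t.p2 for t in accepted_trios}
    for r in retained:
        if (r.inferred_role == "n_gamete_parent"
                and r.candidate not in confirmed_n):
            r.inferred_role = "sib_or_unresolved"
    return {"scan": scan, "retained": retained, "p2n_candidates": p2n_cands,
            "trios": trios, "accepted_trios": accepted_trios,
            "exclusions": exclusions}
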