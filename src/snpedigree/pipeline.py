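"""End-to-end orchestration of the pedigree-reconstruction analysis.

Stages, in order:

1. relatedness prefilter — PI_HAT on all diploid pairs, keep > threshold;
2. duo pass 1 — opposing-homozygote ME on the initial panel, liberal
   acceptance rate;
3. SNP blacklist — drop SNPs erring in two or more accepted duos
   (recurrent per-marker errors, e.g. null alleles);
4. duo pass 2 — ME recounted on the retained panel, final rate;
5. trios — every individual in >= 2 accepted duos tested against each
   pair of its partners;
6. orientation — trio membership, then documented parentage and dates,
   propagated to a fixed point;
7. grandparent search — two-stage (random subpanel, then full panel) for
   duos without a second parent;
8. triploids — exhaustive duo scan, 2n/n-gamete parent assignment, trio
   and parent-exclusion tests;
9. pedigree assembly and statistics.

Thresholds are configured as per-SNP rates; every stage records the
realized absolute threshold so runs on panels of different sizes remain
comparable.  Mapping-population progenies (``exclude`` ids) are kept out
of the network, the grandparent search and the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import exclusion, genotype_io, orientation, pedigree, relatedness, triploid
from .exclusion import ThresholdConfig
from .genotype_io import GenotypeMatrix


@dataclass
class PipelineConfig:
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    subpanel_fraction: float = 0.1
    gp_pi_hat_min: float = 0.15
    gp_exhaustive: bool = False
    min_overlap: int = 1000
    maf_min: float = 0.01
    min_year_gap: int = 10
    exclude: set[str] = field(default_factory=set)


@dataclass
class PipelineRun:
    config: PipelineConfig
    counts: dict = field(default_factory=dict)
    thresholds_realized: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    candidate_pairs: list = field(default_factory=list)
    duos_pass1: list = field(default_factory=list)
    blacklist: object = None
    duos: list = field(default_factory=list)           # accepted, final panel
    trios: list = field(default_factory=list)          # accepted
    all_trios: list = field(default_factory=list)
    oriented_duos: list = field(default_factory=list)
    gp_groups: list = field(default_factory=list)
    triploid_analyses: dict = field(default_factory=dict)
    pedigree: object = None
    pedigree_stats: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    orientation_summary: dict = field(default_factory=dict)

    def note(self, msg: str) -> None:
        self.log.append(msg)


def run_all(matrix: GenotypeMatrix,
            metadata: dict | None = None,
            config: PipelineConfig | None = None) -> PipelineRun:
    cfg = config or PipelineConfig()
    thr = cfg.thresholds
    run = PipelineRun(config=cfg)

    # 1. relatedness prefilter (diploids only; triploids get their own scan)
    freqs = relatedness.allele_frequencies(matrix)
    ids, pi, _ = relatedness.pairwise_pi_hat(
        matrix, freqs, maf_min=cfg.maf_min, min_overlap=cfg.min_overlap)
    pos = {ind: k for k, ind in enumerate(ids)}
    cand = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if not np.isnan(pi[a, b]) and pi[a, b] > thr.pi_hat_min:
                cand.append((ids[a], ids[b], float(pi[a, b])))
    run.candidate_pairs = cand
    run.counts["prefiltered_pairs"] = len(cand)
    run.note(f"prefilter: {len(cand)} pairs with PI_HAT > {thr.pi_hat_min}")

    # 2. duo pass 1 on the initial panel, liberal rate
    results1 = [exclusion.duo_me(matrix, a, b) for a, b, _ in cand]
    accepted1, t1 = exclusion.classify_duos(
        results1, thr, matrix.n_snps, rate=thr.duo_first_pass_rate)
    run.duos_pass1 = accepted1
    run.thresholds_realized["duo_pass1"] = t1
    run.counts["duos_pass1"] = len(accepted1)
    run.note(f"duo pass 1: {len(accepted1)} accepted below {t1} ME "
             f"on {matrix.n_snps} SNPs")

    # 3. blacklist recurrently erring SNPs
    bl = genotype_io.blacklist_recurrent_error_snps(
        matrix, [(d.a, d.b) for d in accepted1], min_relationships=2)
    run.blacklist = bl
    run.counts["blacklisted_snps"] = len(bl.removed_snp_ids)
    keep_idx = matrix.panel.index_of(bl.retained.snp_ids)
    matrix2 = matrix.subset_snps(keep_idx)
    run.note(f"blacklist: removed {len(bl.removed_snp_ids)} SNPs, "
             f"{matrix2.n_snps} retained")

    # 4. duo pass 2 on the retained panel
    results2 = [exclusion.duo_me(matrix2, d.a, d.b) for d in accepted1]
    duos, t2 = exclusion.classify_duos(results2, thr, matrix2.n_snps)
    run.duos = duos
    run.thresholds_realized["duo_pass2"] = t2
    run.counts["duos"] = len(duos)
    run.note(f"duo pass 2: {len(duos)} accepted below {t2} ME "
             f"on {matrix2.n_snps} SNPs")
    run.counts["duo_me_histogram_gap"] = exclusion.me_histogram(
        [d.me_count for d in results2]).attrs.get("largest_gap")

    # 5. trios
    cand_trios = exclusion.enumerate_candidate_trios(duos)
    all_trios = [exclusion.trio_me(matrix2, o, p1, p2)
                 for o, p1, p2 in cand_trios]
    trios, t3 = exclusion.classify_trios(all_trios, thr, matrix2.n_snps)
    run.all_trios = all_trios
    run.trios = trios
    run.thresholds_realized["trio"] = t3
    run.counts["candidate_trios"] = len(cand_trios)
    run.counts["trios"] = len(trios)
    run.note(f"trios: {len(trios)} of {len(cand_trios)} candidates "
             f"accepted below {t3} ME")

    # 6. orientation
    oriented = orientation.orient_from_trios(duos, trios)
    if metadata:
        orientation.orient_from_metadata(oriented, metadata,
                                         cfg.min_year_gap, trios)
    run.oriented_duos = oriented

    # 7. grandparent search for duos without a second parent
    sub = genotype_io.random_subpanel(matrix2.panel, cfg.subpanel_fraction,
                                      cfg.seed)
    sub_idx = matrix2.panel.index_of(sub.snp_ids)
    orphan = [(d.offspring, d.parent, True) if d.oriented
              else (d.a, d.b, False) for d in oriented]
    if cfg.gp_exhaustive:
        lookup = None
    else:
        def lookup(off, _pos=pos, _pi=pi, _ids=ids, _min=cfg.gp_pi_hat_min):
            if off not in _pos:
                return []
            r = _pi[_pos[off]]
            return [_ids[k] for k in np.flatnonzero(~np.isnan(r) & (r >= _min))
                    if _ids[k] != off]
    gp = exclusion.grandparent_search(matrix2, orphan, sub_idx, thr,
                                      candidate_lookup=lookup,
                                      exclude=cfg.exclude)
    run.gp_groups = gp
    run.thresholds_realized["gp_stage1"] = ThresholdConfig.absolute(
        thr.gp_stage1_rate, len(sub_idx))
    run.thresholds_realized["gp_stage2"] = ThresholdConfig.absolute(
        thr.gp_stage2_rate, matrix2.n_snps)
    run.counts["grandparent_groups"] = len(gp)
    run.note(f"grandparents: {len(gp)} groups accepted "
             f"(stage thresholds {run.thresholds_realized['gp_stage1']}, "
             f"{run.thresholds_realized['gp_stage2']})")

    # a grandparent group fixes the roles within its duo: the member with
    # the inferred grandparent couple is the offspring
    gp_orient: dict[frozenset, set[tuple[str, str]]] = {}
    for g in gp:
        gp_orient.setdefault(frozenset((g.offspring, g.parent)),
                             set()).add((g.parent, g.offspring))
    for d in oriented:
        if not d.oriented and d.pair in gp_orient:
            props = gp_orient[d.pair]
            if len(props) == 1:
                par, off = next(iter(props))
                d.orient(par, off, "grandparent_group")
            else:
                d.conflicts.append(
                    "grandparent couples accepted for both orientations")
    orientation.check_acyclic(oriented, trios)
    run.orientation_summary = orientation.orientation_report(oriented)
    run.counts["oriented_duos"] = run.orientation_summary["n_oriented"]
    run.counts["unoriented_duos"] = run.orientation_summary["n_unoriented"]

    # 8. triploids
    for t in matrix2.triploid_ids():
        run.triploid_analyses[t] = triploid.analyze_triploid(
            matrix2, t, thr, exclude=cfg.exclude)
    run.counts["triploid_trios"] = sum(
        len(a["accepted_trios"]) for a in run.triploid_analyses.values())

    # 9. pedigree + network; only grandparent groups whose duo orientation
    # stands (offspring role confirmed) contribute a placeholder parent
    oriented_off = {d.pair: d.offspring for d in oriented if d.oriented}
    gp_for_ped = [g for g in gp
                  if oriented_off.get(frozenset((g.offspring, g.parent)))
                  == g.offspring]
    ped = pedigree.build_pedigree(trios, oriented, gp_for_ped,
                                  exclude=cfg.exclude)
    run.pedigree = ped
    run.pedigree_stats = ped.stats()
    run.network = pedigree.duo_network_components(duos, exclude=cfg.exclude)
    run.counts["pedigree_nodes"] = run.pedigree_stats["n_nodes"]
    run.counts["pedigree_founders"] = run.pedigree_stats["n_founders"]
    run.counts["pedigree_generations"] = run.pedigree_stats["max_generations"]
    run.note(f"pedigree: {run.pedigree_stats['n_nodes']} nodes, "
             f"{run.pedigree_stats['n_founders']} founders, "
             f"{run.pedigree_stats['max_generations']} generations")
    return run
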