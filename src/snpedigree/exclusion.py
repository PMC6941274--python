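"""Mendelian-error exclusion tests for duos, trios and grandparent groups.

A Mendelian error (ME) is a genotype configuration impossible under the
hypothesized relationship at a biallelic SNP:

* duo (putative parent-offspring pair): opposing homozygotes — one
  individual homozygous reference, the other homozygous alternate;
* trio (offspring + two putative parents): an opposing-homozygote
  conflict between the offspring and either parent, OR a heterozygous
  offspring whose two putative parents are homozygous for the same
  allele (no gamete pair can produce the heterozygote);
* grandparent group (offspring + one accepted parent + the putative
  parent couple of the missing parent): both grandparents homozygous for
  the same allele while the offspring is homozygous for the alternate
  allele, or heterozygous with the accepted parent homozygous for the
  grandparents' allele (the missing parent would then have had to
  transmit the allele the grandparents cannot supply).

True relationships give near-zero ME; genotyping error makes the counts
small but non-zero, so relationships are accepted below thresholds
expressed as per-SNP rates and converted to absolute counts per panel.
Each SNP contributes at most one ME, and a missing call in any tested
role skips the SNP (no imputation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotype_io import GenotypeMatrix


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdConfig:
    """Acceptance thresholds expressed as ME rates per SNP.

    Defaults reproduce the absolute counts used on the reference panels:
    600 ME on 253,095 SNPs for duos/trios (0.24%), 1000 on 275,223 for
    the liberal first pass (0.36%), 100 on the 25,310-SNP subpanel
    (0.40%) and 100 on the full panel (0.04%) for grandparent groups.
    Absolute thresholds are recomputed as round(rate x panel size) so the
    same configuration scales to panels of any size.
    """

    duo_me_rate: float = 600 / 253_095
    duo_first_pass_rate: float = 1000 / 275_223
    trio_me_rate: float = 600 / 253_095
    gp_stage1_rate: float = 100 / 25_310
    gp_stage2_rate: float = 100 / 253_095
    pi_hat_min: float = 0.4
    triploid_duo_rate: float = 300 / 253_095
    tri_hom_di_het_rate: float = 1200 / 253_095
    triploid_trio_rate: float = 300 / 253_095

    def __post_init__(self):
        for name in ("duo_me_rate", "duo_first_pass_rate", "trio_me_rate",
                     "gp_stage1_rate", "gp_stage2_rate", "triploid_duo_rate",
                     "tri_hom_di_het_rate", "triploid_trio_rate"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")

    @staticmethod
    def absolute(rate: float, panel_size: int) -> int:
        """Absolute ME threshold realized on a panel; acceptance is
        strict less-than this count.  Floored at 1 so that error-free
        relationships (0 ME) are always accepted."""
        return max(1, int(round(rate * panel_size)))

    @classmethod
    def for_error_rate(cls, eps: float, pi_hat_min: float = 0.4
                       ) -> "ThresholdConfig":
        """Threshold rates matched to a known per-call error rate.

        The method places acceptance thresholds in the gap of the ME
        distribution, between the error-driven counts of true
        relationships and the counts of the nearest competing
        relationship.  Under uniform per-call misclassification with
        probability eps, a single miscall turns a true parent-offspring
        pair into opposing homozygotes at rate ~0.65 eps per SNP
        (both-homozygous-same SNPs contribute eps, homozygote-heterozygote
        SNPs eps/2), and a true trio violates one of the trio conditions
        at ~1.5 eps per SNP; the competing relationships (full sibs for
        duos, parent+grandparent pairings for trios) sit an order of
        magnitude higher, around 0.5 E[(2pq)^2/4] per SNP.  The rates
        below put thresholds 3-5x above the error-driven mean and well
        below those floors.  A small positive floor keeps the rates valid
        for error-free data (where every true relationship has exactly
        0 ME).
        """
        base = max(eps, 1e-4)
        return cls(
            duo_me_rate=3.0 * base,
            duo_first_pass_rate=5.0 * base,
            trio_me_rate=4.5 * base,
            gp_stage1_rate=4.0 * base,
            gp_stage2_rate=3.0 * base,
            pi_hat_min=pi_hat_min,
            triploid_duo_rate=3.0 * base,
            tri_hom_di_het_rate=4.0 * base,
            triploid_trio_rate=4.5 * base,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump({k: float(v) for k, v in self.__dict__.items()},
                              sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ThresholdConfig":
        return cls(**yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class DuoResult:
    a: str
    b: str
    me_count: int
    n_informative: int
    per_chromosome_me: dict[int, int]
    accepted: bool | None = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class TrioResult:
    offspring: str
    p1: str
    p2: str
    me_count: int
    n_informative: int
    accepted: bool | None = None


@dataclass
class GrandparentGroupResult:
    offspring: str
    parent: str
    gp1: str
    gp2: str
    me_stage1: int
    me_stage2: int | None = None
    accepted: bool = False
    comparator: str = "<"  # acceptance comparator, recorded for the report


# ---------------------------------------------------------------------------
# Duos
# ---------------------------------------------------------------------------

def _informative_mask(*rows) -> np.ndarray:
    mask = rows[0] >= 0
    for r in rows[1:]:
        mask = mask & (r >= 0)
    return mask


def duo_me(matrix: GenotypeMatrix, a: str, b: str,
           snp_indices: np.ndarray | None = None) -> DuoResult:
    """Opposing-homozygote count for a putative parent-offspring pair,
    with a per-chromosome breakdown."""
    if a == b:
        raise ValueError("duo requires two distinct individuals")
    ga = matrix.calls[matrix.row(a)]
    gb = matrix.calls[matrix.row(b)]
    chrom = matrix.panel.chromosome
    if snp_indices is not None:
        ga, gb, chrom = ga[snp_indices], gb[snp_indices], chrom[snp_indices]
    mask = _informative_mask(ga, gb)
    if not mask.any():
        raise InsufficientDataError(f"pair ({a},{b}): no informative SNPs")
    err = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
    per_chrom = {}
    for c in np.unique(chrom[err]):
        per_chrom[int(c)] = int((err & (chrom == c)).sum())
    return DuoResult(a, b, int(err.sum()), int(mask.sum()), per_chrom)


def classify_duos(duo_results: list[DuoResult], config: ThresholdConfig,
                  panel_size: int, rate: float | None = None
                  ) -> tuple[list[DuoResult], int]:
    """Mark duos accepted iff me_count < round(rate x panel_size);
    returns (accepted list, realized absolute threshold)."""
    r = config.duo_me_rate if rate is None else rate
    thr = ThresholdConfig.absolute(r, panel_size)
    accepted = []
    for d in duo_results:
        d.accepted = d.me_count < thr
        if d.accepted:
            accepted.append(d)
    return accepted, thr


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------

def enumerate_candidate_trios(accepted_duos: list[DuoResult]
                              ) -> list[tuple[str, str, str]]:
    """Every individual in >= 2 accepted duos is tested as offspring
    against each unordered pair of its duo partners."""
    partners: dict[str, set[str]] = {}
    for d in accepted_duos:
        partners.setdefault(d.a, set()).add(d.b)
        partners.setdefault(d.b, set()).add(d.a)
    out = []
    for ind in sorted(partners):
        ps = sorted(partners[ind])
        for p1, p2 in itertools.combinations(ps, 2):
            out.append((ind, p1, p2))
    return out


def trio_me(matrix: GenotypeMatrix, offspring: str, p1: str, p2: str,
            snp_indices: np.ndarray | None = None) -> TrioResult:
    """Trio ME count: at most one error per SNP; a SNP with a missing
    call in any of the three roles is skipped."""
    if len({offspring, p1, p2}) != 3:
        raise ValueError("trio requires three distinct individuals")
    go = matrix.calls[matrix.row(offspring)]
    g1 = matrix.calls[matrix.row(p1)]
    g2 = matrix.calls[matrix.row(p2)]
    if snp_indices is not None:
        go, g1, g2 = go[snp_indices], g1[snp_indices], g2[snp_indices]
    mask = _informative_mask(go, g1, g2)
    if not mask.any():
        raise InsufficientDataError("trio has no informative SNPs")
    opp = lambda x, y: ((x == 0) & (y == 2)) | ((x == 2) & (y == 0))
    het_bothhom = (go == 1) & (((g1 == 0) & (g2 == 0)) | ((g1 == 2) & (g2 == 2)))
    err = mask & (opp(go, g1) | opp(go, g2) | het_bothhom)
    return TrioResult(offspring, p1, p2, int(err.sum()), int(mask.sum()))


def classify_trios(trio_results: list[TrioResult], config: ThresholdConfig,
                   panel_size: int) -> tuple[list[TrioResult], int]:
    thr = ThresholdConfig.absolute(config.trio_me_rate, panel_size)
    accepted = []
    for t in trio_results:
        t.accepted = t.me_count < thr
        if t.accepted:
            accepted.append(t)
    return accepted, thr


# ---------------------------------------------------------------------------
# Grandparent groups
# ---------------------------------------------------------------------------

def grandparent_me(matrix: GenotypeMatrix, offspring: str, parent: str,
                   gp1: str, gp2: str,
                   snp_indices: np.ndarray | None = None) -> int:
    """ME count for a grandparents-parent-offspring hypothesis (the
    grandparent couple are the parents of the offspring's missing
    parent).  Missing calls in any of the four roles skip the SNP."""
    if len({offspring, parent, gp1, gp2}) != 4:
        raise ValueError("grandparent group requires four distinct individuals")
    go = matrix.calls[matrix.row(offspring)]
    gp = matrix.calls[matrix.row(parent)]
    a = matrix.calls[matrix.row(gp1)]
    b = matrix.calls[matrix.row(gp2)]
    if snp_indices is not None:
        go, gp = go[snp_indices], gp[snp_indices]
        a, b = a[snp_indices], b[snp_indices]
    mask = _informative_mask(go, gp, a, b)
    err = np.zeros(len(go), dtype=bool)
    for hom in (0, 2):
        alt = 2 - hom
        gps_hom = (a == hom) & (b == hom)
        err |= gps_hom & ((go == alt) | ((go == 1) & (gp == hom)))
    return int((err & mask).sum())


def grandparent_search(matrix: GenotypeMatrix,
                       orphan_duos: list[tuple[str, str, bool]],
                       subpanel_indices: np.ndarray,
                       config: ThresholdConfig,
                       candidate_lookup=None,
                       exclude: set[str] | None = None,
                       ) -> list[GrandparentGroupResult]:
    """Two-stage search for the parent couple of a missing parent.

    ``orphan_duos`` holds (offspring, parent, oriented) triples for
    accepted duos not absorbed into trios; when ``oriented`` is False
    both role assignments of the pair are tested.  Stage 1 screens all
    candidate grandparent couples on the random subpanel (ME strictly
    below round(gp_stage1_rate x subpanel size)); stage 2 recomputes
    survivors on the full panel (strictly below
    round(gp_stage2_rate x panel size)).

    ``candidate_lookup`` maps an offspring id to the iterable of
    candidate grandparent ids (e.g. individuals with PI_HAT >= 0.15 to
    the offspring); None means exhaustive over all diploids.  Triploids
    are never candidates; ids in ``exclude`` (e.g. mapping-population
    progenies) are skipped entirely.
    """
    exclude = exclude or set()
    diploids = [i for i in matrix.diploid_ids() if i not in exclude]
    thr1 = ThresholdConfig.absolute(config.gp_stage1_rate, len(subpanel_indices))
    thr2 = ThresholdConfig.absolute(config.gp_stage2_rate, matrix.n_snps)
    results: list[GrandparentGroupResult] = []
    seen: set[tuple] = set()
    for off, par, oriented in orphan_duos:
        if off in exclude or par in exclude:
            continue
        orientations = [(off, par)] if oriented else [(off, par), (par, off)]
        for o, p in orientations:
            if candidate_lookup is None:
                cands = diploids
            else:
                cands = list(candidate_lookup(o))
            cands = [c for c in cands if c not in (o, p) and c not in exclude
                     and matrix.is_diploid(c)]
            for gp1, gp2 in itertools.combinations(sorted(cands), 2):
                key = (o, p, gp1, gp2)
                if key in seen:
                    continue
                seen.add(key)
                me1 = grandparent_me(matrix, o, p, gp1, gp2, subpanel_indices)
                if me1 >= thr1:
                    continue
                me2 = grandparent_me(matrix, o, p, gp1, gp2)
                res = GrandparentGroupResult(o, p, gp1, gp2, me1, me2,
                                             accepted=me2 < thr2)
                if res.accepted:
                    results.append(res)
    return results


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def per_chromosome_me_report(duo_results: list[DuoResult],
                             max_fraction: float = 0.5,
                             top_chromosomes: int = 2,
                             min_me: int = 10) -> pd.DataFrame:
    """Flag duos whose ME cluster on one or two chromosomes.

    Clustered errors are the signature of null-allele segments (e.g.
    introgressed chromosomal fragments with diverged sequence) rather
    than a wrong relationship.  A duo is flagged when more than
    ``max_fraction`` of its ME fall on at most ``top_chromosomes``
    chromosomes and it carries at least ``min_me`` errors.
    """
    rows = []
    for d in duo_results:
        total = d.me_count
        if total == 0:
            continue
        counts = sorted(d.per_chromosome_me.items(), key=lambda kv: -kv[1])
        top = counts[:top_chromosomes]
        top_sum = sum(c for _, c in top)
        max_frac = counts[0][1] / total
        flagged = (total >= min_me) and (top_sum / total > max_fraction)
        rows.append({"a": d.a, "b": d.b, "me": total,
                     "max_chrom": counts[0][0], "max_fraction": max_frac,
                     "top_chromosomes": [c for c, _ in top],
                     "top_fraction": top_sum / total, "flagged": flagged})
    return pd.DataFrame(rows, columns=["a", "b", "me", "max_chrom",
                                       "max_fraction", "top_chromosomes",
                                       "top_fraction", "flagged"])


def me_histogram(counts: list[int], bin_width: int = 50) -> pd.DataFrame:
    """ME-count histogram plus the largest empty interval (the 'gap'
    heuristic used to place thresholds by inspection — reported, never
    applied automatically)."""
    if not counts:
        return pd.DataFrame(columns=["bin_left", "count"])
    arr = np.sort(np.asarray(counts))
    bins = np.arange(0, arr.max() + bin_width + 1, bin_width)
    hist, edges = np.histogram(arr, bins=bins)
    df = pd.DataFrame({"bin_left": edges[:-1], "count": hist})
    gaps = np.diff(arr)
    if len(gaps) and gaps.max() > 0:
        k = int(np.argmax(gaps))
        df.attrs["largest_gap"] = (int(arr[k]), int(arr[k + 1]))
    return df
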