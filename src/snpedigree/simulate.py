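"""Gene-dropping simulator for multi-generation germplasm cohorts.

Founders are drawn in Hardy-Weinberg proportions from a configurable
allele-frequency spectrum; later generations receive one allele per
parent per SNP (unlinked loci — linkage is irrelevant to per-SNP
exclusion counts, but SNPs still carry chromosome labels so clustered
null-allele diagnostics are testable).  Parent pairs are sampled from
earlier generations with optional preferential attachment, which creates
the hub cultivars (a few individuals with many offspring) typical of
clonal germplasm.

On top of the clean transmission the simulator layers the blemishes the
exclusion pipeline must survive: per-call genotyping error (uniform
misclassification into one of the other genotype classes), missingness,
a null-allele-like segment that silently converts heterozygotes to
homozygotes on one chromosome for a subset of individuals, triploids
formed from a 2n gamete plus an n gamete, and passport metadata whose
dates and parentages are partially missing and partially wrong.

Everything emitted is reproducible from the seed, and the TruthSet
records what was planted so every pipeline stage can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np

from .genotype_io import CultivarMetadata, GenotypeMatrix, SNPPanel


class ConfigError(ValueError):
    pass


@dataclass
class NullAlleleSpec:
    """A clustered-error segment: heterozygous calls of the affected
    individuals become homozygous-reference within the span (emulating a
    null alternate allele in a diverged chromosomal fragment)."""
    chromosome: int = 13
    start_fraction: float = 0.0
    end_fraction: float = 1.0
    n_affected: int = 2


@dataclass
class SimulationConfig:
    n_founders: int = 60
    n_generations: int = 4            # founders are generation 1
    offspring_per_generation: int = 50
    n_snps: int = 5000
    n_chromosomes: int = 17
    maf_range: tuple = (0.05, 0.5)
    error_rate: float = 0.002
    missing_rate: float = 0.005
    null_allele: NullAlleleSpec | None = None
    n_triploids: int = 0
    triploid_reassortment: float = 0.0
    preferential_attachment: float = 1.0
    founder_year_range: tuple = (1500, 1700)
    generation_gap_range: tuple = (20, 60)
    date_missing_rate: float = 0.2
    date_wrong_rate: float = 0.1
    date_approximate_rate: float = 0.1
    parentage_documented_rate: float = 0.3
    parentage_wrong_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.n_generations > 1 and self.n_founders < 2:
            raise ConfigError("need >= 2 founders for multiple generations")
        for name in ("error_rate", "missing_rate", "date_missing_rate",
                     "date_wrong_rate", "date_approximate_rate",
                     "parentage_documented_rate", "parentage_wrong_rate",
                     "triploid_reassortment"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0,1], got {v}")


@dataclass
class TruthSet:
    """Ground truth for a simulated cohort."""
    pedigree: dict[str, tuple[str, str]]          # child -> (p1, p2)
    generation: dict[str, int]                    # 1 = founder
    triploid_gametes: dict[str, tuple[str, str]]  # triploid -> (2n parent, n parent)
    true_dates: dict[str, int]
    wrong_date_ids: set[str] = field(default_factory=set)
    missing_date_ids: set[str] = field(default_factory=set)
    wrong_parentage_ids: set[str] = field(default_factory=set)
    n_error_calls: int = 0
    null_allele_snps: list[str] = field(default_factory=list)
    null_allele_affected: list[str] = field(default_factory=list)

    # -- convenience views ---------------------------------------------------

    def true_duos(self) -> set[frozenset]:
        return {frozenset((c, p)) for c, ps in self.pedigree.items()
                for p in ps}

    def true_trios(self) -> set[tuple[str, frozenset]]:
        return {(c, frozenset(ps)) for c, ps in self.pedigree.items()}

    def ancestors(self, ind: str) -> set[str]:
        out, stack = set(), [ind]
        while stack:
            x = stack.pop()
            for p in self.pedigree.get(x, ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def unrelated(self, a: str, b: str) -> bool:
        aa = self.ancestors(a) | {a}
        bb = self.ancestors(b) | {b}
        return not (aa & bb)

    def half_sib_pairs(self) -> set[frozenset]:
        """Pairs sharing exactly one parent (and not otherwise first
        degree)."""
        out = set()
        kids = list(self.pedigree)
        for i, a in enumerate(kids):
            for b in kids[i + 1:]:
                shared = set(self.pedigree[a]) & set(self.pedigree[b])
                if len(shared) == 1 and frozenset((a, b)) not in self.true_duos():
                    out.add(frozenset((a, b)))
        return out

    def to_json(self, path) -> None:
        data = {
            "pedigree": {k: list(v) for k, v in self.pedigree.items()},
            "generation": self.generation,
            "triploid_gametes": {k: list(v) for k, v in
                                 self.triploid_gametes.items()},
            "true_dates": self.true_dates,
            "wrong_date_ids": sorted(self.wrong_date_ids),
            "missing_date_ids": sorted(self.missing_date_ids),
            "wrong_parentage_ids": sorted(self.wrong_parentage_ids),
            "n_error_calls": self.n_error_calls,
            "null_allele_snps": self.null_allele_snps,
            "null_allele_affected": self.null_allele_affected,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pedigree={k: tuple(v) for k, v in d["pedigree"].items()},
            generation=d["generation"],
            triploid_gametes={k: tuple(v) for k, v in
                              d["triploid_gametes"].items()},
            true_dates=d["true_dates"],
            wrong_date_ids=set(d["wrong_date_ids"]),
            missing_date_ids=set(d["missing_date_ids"]),
            wrong_parentage_ids=set(d["wrong_parentage_ids"]),
            n_error_calls=d["n_error_calls"],
            null_allele_snps=d["null_allele_snps"],
            null_allele_affected=d["null_allele_affected"],
        )


def _make_panel(cfg: SimulationConfig) -> SNPPanel:
    ids = np.array([f"SNP{i:06d}" for i in range(cfg.n_snps)], dtype=object)
    chrom = 1 + (np.arange(cfg.n_snps) * cfg.n_chromosomes) // cfg.n_snps
    pos = np.zeros(cfg.n_snps, dtype=np.int64)
    for c in range(1, cfg.n_chromosomes + 1):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = (np.arange(len(idx)) + 1) * 10_000
    return SNPPanel(ids, chrom, pos)


def _gamete(geno: np.ndarray, rng) -> np.ndarray:
    """One allele per SNP from a diploid genotype (dosage form)."""
    g = np.zeros(len(geno), dtype=np.int8)
    g[geno == 2] = 1
    het = geno == 1
    g[het] = rng.integers(0, 2, size=het.sum(), dtype=np.int8)
    return g


def simulate(config: SimulationConfig
             ) -> tuple[GenotypeMatrix, dict[str, CultivarMetadata], TruthSet]:
    """Generate (genotype matrix, metadata, truth set) for one cohort."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    panel = _make_panel(cfg)

    # founders in HWE
    p = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    ids: list[str] = []
    genos: list[np.ndarray] = []
    generation: dict[str, int] = {}
    pedigree: dict[str, tuple[str, str]] = {}
    n_offspring = np.zeros(0, dtype=np.int64)  # grows with cohort

    def add_individual(name, geno, gen):
        nonlocal n_offspring
        ids.append(name)
        genos.append(geno)
        generation[name] = gen
        n_offspring = np.append(n_offspring, 0)

    for i in range(cfg.n_founders):
        g = rng.binomial(2, p).astype(np.int8)
        add_individual(f"F{i + 1:04d}", g, 1)

    counter = 0
    for gen in range(2, cfg.n_generations + 1):
        pool = [k for k, name in enumerate(ids) if generation[name] < gen]
        weights = 1.0 + cfg.preferential_attachment * n_offspring[pool]
        for _ in range(cfg.offspring_per_generation):
            wp = weights / weights.sum()
            k1, k2 = rng.choice(len(pool), size=2, replace=False, p=wp)
            i1, i2 = pool[k1], pool[k2]
            child = _gamete(genos[i1], rng) + _gamete(genos[i2], rng)
            counter += 1
            name = f"G{gen}_{counter:04d}"
            add_individual(name, child, gen)
            pedigree[name] = (ids[i1], ids[i2])
            n_offspring[i1] += 1
            n_offspring[i2] += 1
            weights[k1] += cfg.preferential_attachment
            weights[k2] += cfg.preferential_attachment

    # triploids: 2n gamete = full parental genotype (optional per-SNP
    # reassortment of heterozygous loci to a homozygous contribution),
    # plus one allele from the n-gamete parent
    triploid_gametes: dict[str, tuple[str, str]] = {}
    n_diploids = len(ids)
    for t in range(cfg.n_triploids):
        k2n, kn = rng.choice(n_diploids, size=2, replace=False)
        g2n = genos[k2n].astype(np.int8).copy()
        if cfg.triploid_reassortment > 0:
            het = np.flatnonzero(g2n == 1)
            flip = het[rng.random(len(het)) < cfg.triploid_reassortment]
            g2n[flip] = 2 * rng.integers(0, 2, size=len(flip), dtype=np.int8)
        raw = g2n + _gamete(genos[kn], rng)
        name = f"T{t + 1:04d}"
        add_individual(name, raw, max(generation[ids[k2n]],
                                      generation[ids[kn]]) + 1)
        pedigree[name] = (ids[k2n], ids[kn])
        triploid_gametes[name] = (ids[k2n], ids[kn])

    calls = np.vstack(genos).astype(np.int8)
    ploidy = np.array([3 if name in triploid_gametes else 2 for name in ids],
                      dtype=np.int8)

    # genotyping error: uniform misclassification among the other classes
    n_errors = 0
    if cfg.error_rate > 0:
        err_mask = rng.random(calls.shape) < cfg.error_rate
        rows, cols = np.nonzero(err_mask)
        for r, c in zip(rows, cols):
            classes = [0, 1, 2, 3] if ploidy[r] == 3 else [0, 1, 2]
            classes = [x for x in classes if x != calls[r, c]]
            calls[r, c] = classes[rng.integers(0, len(classes))]
        n_errors = len(rows)

    # null-allele segment: HET -> HOM_REF in the span for affected ids
    null_snps: list[str] = []
    null_affected: list[str] = []
    if cfg.null_allele is not None:
        spec = cfg.null_allele
        on_chrom = np.flatnonzero(panel.chromosome == spec.chromosome)
        lo = int(spec.start_fraction * len(on_chrom))
        hi = int(spec.end_fraction * len(on_chrom))
        span = on_chrom[lo:hi]
        null_snps = [str(s) for s in panel.snp_ids[span]]
        nonfounders = [k for k, name in enumerate(ids)
                       if generation[name] > 1 and ploidy[k] == 2]
        chosen = rng.choice(nonfounders,
                            size=min(spec.n_affected, len(nonfounders)),
                            replace=False)
        for k in chosen:
            het = span[calls[k, span] == 1]
            calls[k, het] = 0
            null_affected.append(ids[k])

    # missingness
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = -1

    matrix = GenotypeMatrix(ids, panel, calls, ploidy)

    # dates: child strictly younger than both parents
    true_dates: dict[str, int] = {}
    for name in ids:
        if generation[name] == 1:
            true_dates[name] = int(rng.integers(*cfg.founder_year_range))
    for gen in range(2, max(generation.values()) + 1):
        for name in ids:
            if generation[name] == gen and name in pedigree:
                pmax = max(true_dates[q] for q in pedigree[name])
                true_dates[name] = pmax + int(
                    rng.integers(*cfg.generation_gap_range))

    # metadata with planted corruption
    meta: dict[str, CultivarMetadata] = {}
    wrong_date_ids, missing_date_ids, wrong_parentage_ids = set(), set(), set()
    for k, name in enumerate(ids):
        date: int | None = true_dates[name]
        precision = "precise"
        u = rng.random()
        if u < cfg.date_missing_rate:
            date, precision = None, "unknown"
            missing_date_ids.add(name)
        elif u < cfg.date_missing_rate + cfg.date_wrong_rate:
            # planted wrong date: pushed before the founder era so it
            # collides with ancestors' dates
            date = int(true_dates[name]
                       - rng.integers(*cfg.generation_gap_range)
                       - (true_dates[name] - cfg.founder_year_range[0]))
            wrong_date_ids.add(name)
        elif u < (cfg.date_missing_rate + cfg.date_wrong_rate
                  + cfg.date_approximate_rate):
            precision = "approximate"
        p1 = p2 = None
        if name in pedigree:
            v = rng.random()
            if v < cfg.parentage_documented_rate:
                p1, p2 = pedigree[name]
            elif v < cfg.parentage_documented_rate + cfg.parentage_wrong_rate:
                p1 = ids[int(rng.integers(0, len(ids)))]
                if p1 in (name, *pedigree[name]):
                    p1 = None
                else:
                    wrong_parentage_ids.add(name)
        meta[name] = CultivarMetadata(munq=name, preferred_name=name,
                                      ploidy=int(ploidy[k]), date=date,
                                      date_precision=precision,
                                      parent1=p1, parent2=p2)

    truth = TruthSet(pedigree=pedigree, generation=generation,
                     triploid_gametes=triploid_gametes,
                     true_dates=true_dates, wrong_date_ids=wrong_date_ids,
                     missing_date_ids=missing_date_ids,
                     wrong_parentage_ids=wrong_parentage_ids,
                     n_error_calls=n_errors, null_allele_snps=null_snps,
                     null_allele_affected=null_affected)
    return matrix, meta, truth


def mask_individuals(matrix: GenotypeMatrix, ids: list[str]
                     ) -> GenotypeMatrix:
    """Drop individuals from the matrix (the truth pedigree keeps them),
    creating the missing-parent scenario the grandparent search targets."""
    for i in ids:
        matrix.row(i)  # raises KeyError for unknown ids
    keep = [i for i in matrix.individuals if i not in set(ids)]
    return matrix.subset_individuals(keep)
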