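"""Genotype matrices, SNP panels and cultivar metadata.

Genotypes are biallelic SNP calls stored as the dosage of the alternate
allele: 0 (homozygous reference), 1 (heterozygous), 2 (homozygous
alternate), with ``MISSING`` (-1) as a distinct sentinel.  Triploid
individuals additionally carry a raw {0,1,2,3} dosage layer; the working
``calls`` layer always holds the pseudo-diploid recoding (0->0, 1,2->1,
3->2) so that every downstream exclusion test can treat all individuals
as diploid.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = np.int8(-1)

#: tokens normalised to MISSING at read time
MISSING_TOKENS = {"NA", "na", "-", "./.", ".", ""}


class FormatError(ValueError):
    """Malformed input file (row length, bad token, odd allele count...)."""


class ValidationError(ValueError):
    """Structurally invalid data (duplicate ids, bad ploidy, bad dosage)."""


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPPanel:
    """An ordered set of SNPs with map positions.

    Chromosomes 1-17 are the nuclear chromosomes; 18 marks unanchored
    contigs and 19 unplaced SNPs, following the convention of apple
    genome builds.
    """

    snp_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.snp_ids, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        object.__setattr__(self, "snp_ids", ids)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)
        if not (len(ids) == len(chrom) == len(pos)):
            raise ValidationError("panel arrays have unequal lengths")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP ids in panel")
        if len(chrom) and (chrom.min() < 1 or chrom.max() > 19):
            raise ValidationError("chromosome labels must lie in 1..19")
        if len(pos) and pos.min() < 0:
            raise ValidationError("negative bp position")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, indices: np.ndarray) -> "SNPPanel":
        idx = np.asarray(indices)
        return SNPPanel(self.snp_ids[idx], self.chromosome[idx],
                        self.position_bp[idx])

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"SNP {exc.args[0]!r} not in panel") from exc

    @classmethod
    def default(cls, n_snps: int) -> "SNPPanel":
        """Positionless panel (chromosome 19 = unplaced)."""
        ids = np.array([f"SNP{i:06d}" for i in range(n_snps)], dtype=object)
        return cls(ids, np.full(n_snps, 19), np.zeros(n_snps, dtype=np.int64))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Individuals x SNPs dosage calls with ploidy flags and a SNP map.

    Parameters
    ----------
    individuals
        Ordered unique individual ids.
    panel
        The SNP panel (one entry per column).
    raw_calls
        Dosage of the alternate allele; -1 for missing.  Diploid rows must
        lie in {-1,0,1,2}; triploid rows may additionally contain 3.
    ploidy
        Per-individual ploidy, 2 or 3.
    """

    def __init__(self, individuals: Sequence[str], panel: SNPPanel,
                 raw_calls: np.ndarray, ploidy: Sequence[int] | None = None):
        self.individuals = list(individuals)
        if len(set(self.individuals)) != len(self.individuals):
            dups = {x for x in self.individuals if self.individuals.count(x) > 1}
            raise ValidationError(f"duplicate individual id(s): {sorted(dups)}")
        self.panel = panel
        raw = np.asarray(raw_calls, dtype=np.int8)
        if raw.shape != (len(self.individuals), len(panel)):
            raise ValidationError(
                f"call array shape {raw.shape} != "
                f"({len(self.individuals)}, {len(panel)})")
        if ploidy is None:
            ploidy = [2] * len(self.individuals)
        self.ploidy = np.asarray(ploidy, dtype=np.int8)
        if self.ploidy.shape != (len(self.individuals),):
            raise ValidationError("ploidy length mismatch")
        if not np.isin(self.ploidy, (2, 3)).all():
            raise ValidationError("ploidy must be 2 or 3")
        dip = self.ploidy == 2
        if raw[dip].size and (raw[dip].max(initial=0) > 2 or raw[dip].min(initial=0) < -1):
            raise ValidationError("diploid dosage outside {-1,0,1,2}")
        if raw.size and (raw.max(initial=0) > 3 or raw.min(initial=0) < -1):
            raise ValidationError("dosage outside {-1,0,1,2,3}")
        self.raw_calls = raw
        # pseudo-diploid working layer: triploid 1,2 -> HET, 3 -> HOM_ALT
        from .triploid import recode_triploid  # local import, no cycle at runtime
        calls = raw.copy()
        for i in np.flatnonzero(self.ploidy == 3):
            calls[i] = recode_triploid(raw[i], assume_raw=True)
        self.calls = calls
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.panel)

    def row(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def is_diploid(self, individual: str) -> bool:
        return bool(self.ploidy[self.row(individual)] == 2)

    def diploid_ids(self) -> list[str]:
        return [ind for ind, p in zip(self.individuals, self.ploidy) if p == 2]

    def triploid_ids(self) -> list[str]:
        return [ind for ind, p in zip(self.individuals, self.ploidy) if p == 3]

    def subset_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(self.individuals, self.panel.subset(idx),
                              self.raw_calls[:, idx], self.ploidy)

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.row(i) for i in ids]
        return GenotypeMatrix(list(ids), self.panel, self.raw_calls[rows],
                              self.ploidy[rows])

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.individuals == other.individuals
                and np.array_equal(self.raw_calls, other.raw_calls)
                and np.array_equal(self.ploidy, other.ploidy)
                and np.array_equal(self.panel.snp_ids, other.panel.snp_ids))


# ---------------------------------------------------------------------------
# Cultivar metadata
# ---------------------------------------------------------------------------

@dataclass
class CultivarMetadata:
    """Passport data for one genotype: unique code, name, ploidy, documented
    date with a precision flag, and documented parent names (either may be
    unknown)."""

    munq: str
    preferred_name: str
    ploidy: int = 2
    date: int | None = None
    date_precision: str = "unknown"  # precise | approximate | unknown
    parent1: str | None = None
    parent2: str | None = None

    def __post_init__(self):
        if self.ploidy not in (2, 3):
            raise ValidationError(f"{self.munq}: ploidy must be 2 or 3")
        if self.date is not None and not (1 <= int(self.date) <= 2100):
            raise ValidationError(f"{self.munq}: implausible year {self.date}")
        if self.date_precision not in ("precise", "approximate", "unknown"):
            raise ValidationError(
                f"{self.munq}: bad date precision {self.date_precision!r}")

    @property
    def documented_parents(self) -> tuple[str | None, str | None]:
        return (self.parent1, self.parent2)


def read_metadata(path) -> dict[str, CultivarMetadata]:
    """Read the metadata CSV (columns munq, preferred_name, ploidy, date,
    date_precision, parent1, parent2)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[str, CultivarMetadata] = {}
    for _, r in df.iterrows():
        munq = r["munq"]
        if munq in out:
            raise ValidationError(f"duplicate munq {munq!r}")
        out[munq] = CultivarMetadata(
            munq=munq,
            preferred_name=r.get("preferred_name", munq) or munq,
            ploidy=int(r.get("ploidy", "2") or 2),
            date=int(r["date"]) if r.get("date", "") else None,
            date_precision=r.get("date_precision", "") or "unknown",
            parent1=r.get("parent1", "") or None,
            parent2=r.get("parent2", "") or None,
        )
    return out


def write_metadata(meta: dict[str, CultivarMetadata], path) -> None:
    rows = [{"munq": m.munq, "preferred_name": m.preferred_name,
             "ploidy": m.ploidy, "date": m.date if m.date is not None else "",
             "date_precision": m.date_precision,
             "parent1": m.parent1 or "", "parent2": m.parent2 or ""}
            for m in meta.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------

def _parse_dosage_token(tok: str, line_no: int, permissive: bool) -> int:
    if tok in MISSING_TOKENS:
        return -1
    if tok in ("0", "1", "2", "3"):
        return int(tok)
    if permissive:
        return -1
    raise FormatError(f"line {line_no}: unknown genotype token {tok!r}")


def read_matrix(path, format: str = "matrix-tsv", map_path=None,
                permissive: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``matrix-tsv``: header row ``id<TAB>ploidy<TAB><snp ids...>``, one row
    per individual with dosage tokens (0/1/2, 3 for triploids; NA/-/./. =
    missing).  ``plink``: text .ped with 6 leading columns then two allele
    tokens (A/B coding, "0 0" = missing) per SNP, plus the .map file
    (chrom, snp_id, cM ignored, bp); pass the .ped path, the .map is
    located by extension (or give ``map_path``).

    Unknown tokens become MISSING only when ``permissive`` is set,
    otherwise a :class:`FormatError` names the offending line.
    """
    if format == "matrix-tsv":
        return _read_matrix_tsv(path, map_path, permissive)
    if format in ("plink", "plink-ped/map", "ped"):
        return _read_plink(path, map_path, permissive)
    raise ValueError(f"unknown format {format!r}")


def _read_map(map_path) -> SNPPanel:
    rows = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"map line {line_no}: expected 4 columns")
            rows.append((int(parts[0]), parts[1], int(parts[3])))
    return SNPPanel(np.array([r[1] for r in rows], dtype=object),
                    np.array([r[0] for r in rows]),
                    np.array([r[2] for r in rows]))


def _read_matrix_tsv(path, map_path, permissive) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "id" or header[1] != "ploidy":
            raise FormatError("header must be: id, ploidy, <snp ids...>")
        snp_ids = header[2:]
        inds, ploidy, rows = [], [], []
        for line_no, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"line {line_no}: {len(parts)} fields, expected {len(header)}")
            inds.append(parts[0])
            ploidy.append(int(parts[1]))
            rows.append([_parse_dosage_token(t, line_no, permissive)
                         for t in parts[2:]])
    if map_path is not None:
        panel = _read_map(map_path)
        if list(panel.snp_ids) != snp_ids:
            raise FormatError("map SNP ids do not match matrix header")
    else:
        panel = SNPPanel(np.array(snp_ids, dtype=object),
                         np.full(len(snp_ids), 19),
                         np.zeros(len(snp_ids), dtype=np.int64))
    return GenotypeMatrix(inds, panel, np.array(rows, dtype=np.int8), ploidy)


def _read_plink(ped_path, map_path, permissive) -> GenotypeMatrix:
    ped_path = str(ped_path)
    if map_path is None:
        map_path = ped_path[:-4] + ".map" if ped_path.endswith(".ped") \
            else ped_path + ".map"
    panel = _read_map(map_path)
    inds, rows = [], []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            alleles = parts[6:]
            if len(alleles) != 2 * len(panel):
                raise FormatError(
                    f"ped line {line_no}: {len(alleles)} allele tokens, "
                    f"expected {2 * len(panel)} (odd or wrong count)")
            inds.append(parts[1])
            row = []
            for k in range(len(panel)):
                a, b = alleles[2 * k], alleles[2 * k + 1]
                if a == "0" or b == "0":
                    row.append(-1)
                    continue
                dos = 0
                for al in (a, b):
                    if al == "B":
                        dos += 1
                    elif al != "A":
                        if permissive:
                            dos = -1
                            break
                        raise FormatError(
                            f"ped line {line_no}: unknown allele {al!r} "
                            "(expected A/B coding)")
                row.append(dos)
            rows.append(row)
    return GenotypeMatrix(inds, panel, np.array(rows, dtype=np.int8))


def write_matrix(matrix: GenotypeMatrix, path) -> None:
    """Write matrix-tsv; triploid rows keep their raw {0..3} dosages so a
    read round-trips calls and ploidy exactly."""
    with open(path, "w") as fh:
        fh.write("id\tploidy\t" + "\t".join(map(str, matrix.panel.snp_ids)) + "\n")
        for i, ind in enumerate(matrix.individuals):
            toks = ["NA" if c < 0 else str(int(c)) for c in matrix.raw_calls[i]]
            fh.write(f"{ind}\t{int(matrix.ploidy[i])}\t" + "\t".join(toks) + "\n")


def write_map(panel: SNPPanel, path) -> None:
    with open(path, "w") as fh:
        for s, c, p in zip(panel.snp_ids, panel.chromosome, panel.position_bp):
            fh.write(f"{c}\t{s}\t0\t{p}\n")


# ---------------------------------------------------------------------------
# Panel management
# ---------------------------------------------------------------------------

@dataclass
class BlacklistReport:
    retained: SNPPanel
    removed_snp_ids: list[str]
    error_counts: dict[str, int]  # removed snp -> number of duos violated


def blacklist_recurrent_error_snps(matrix: GenotypeMatrix,
                                   accepted_duos: Sequence[tuple[str, str]],
                                   min_relationships: int = 2
                                   ) -> BlacklistReport:
    """Remove SNPs showing an opposing-homozygote error in at least
    ``min_relationships`` accepted parent-offspring duos.

    Recurrent per-SNP errors across independently accepted relationships
    point at the marker (null alleles, clustering artefacts), not at the
    relationships, so such SNPs are dropped from the panel.
    """
    if min_relationships < 1:
        raise ValueError("min_relationships must be >= 1")
    counts = np.zeros(matrix.n_snps, dtype=np.int64)
    for a, b in accepted_duos:
        ga = matrix.calls[matrix.row(a)]
        gb = matrix.calls[matrix.row(b)]
        err = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
        counts += err
    bad = counts >= min_relationships
    removed = [str(s) for s in matrix.panel.snp_ids[bad]]
    report = BlacklistReport(
        retained=matrix.panel.subset(np.flatnonzero(~bad)),
        removed_snp_ids=removed,
        error_counts={s: int(c) for s, c in
                      zip(removed, counts[bad])},
    )
    return report


def random_subpanel(panel: SNPPanel, fraction: float, seed: int) -> SNPPanel:
    """Uniform random subset of floor(fraction * n) SNPs, reproducible from
    the seed.  Rounding is floor by deliberate choice (deterministic and
    documented); panel order is preserved."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(panel)
    k = math.floor(fraction * n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return panel.subset(idx)


# ---------------------------------------------------------------------------
# Heterozygosity and outliers
# ---------------------------------------------------------------------------

@dataclass
class HeterozygosityReport:
    individuals: list[str]
    H: np.ndarray                     # NaN where all calls missing
    all_missing: list[str]
    outliers: list[str] = field(default_factory=list)
    outlier_table: pd.DataFrame | None = None


def heterozygosity(matrix: GenotypeMatrix) -> HeterozygosityReport:
    """Fraction of heterozygous calls among non-missing calls, per
    individual.  Triploids are scored on the pseudo-diploid layer.
    Individuals with no non-missing call get H = NaN and are flagged."""
    nonmiss = (matrix.calls >= 0).sum(axis=1)
    het = (matrix.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    all_missing = [ind for ind, n in zip(matrix.individuals, nonmiss) if n == 0]
    return HeterozygosityReport(list(matrix.individuals), H, all_missing)


@dataclass
class RosnerResult:
    n_outliers: int
    outlier_indices: list[int]
    table: pd.DataFrame  # columns i, value, R, lam, is_outlier


def rosner_outliers(values, alpha: float = 0.05, max_k: int = 10,
                    tail: str = "both") -> RosnerResult:
    """Generalized extreme studentized deviate (Rosner) outlier test.

    Iteratively removes the most extreme value and compares each
    studentized statistic R_i with its t-based critical value lambda_i;
    the declared number of outliers is the LARGEST i with R_i > lambda_i.
    ``tail`` restricts which removals count as outliers when reporting
    ('low', 'high' or 'both'); the test statistics themselves are the
    classical two-sided extreme deviates.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if n <= max_k + 2:
        raise ValueError(f"need n > max_k + 2 (n={n}, max_k={max_k})")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: Rosner test undefined")

    work = x.copy()
    removed_idx: list[int] = []
    order = np.argsort(np.argsort(x))  # stable original indexing helper
    orig_indices = list(range(n))
    rows = []
    for i in range(1, max_k + 1):
        m, s = work.mean(), work.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(work - m)
        j = int(np.argmax(dev))
        R = dev[j] / s
        ni = len(work)
        p = 1 - alpha / (2 * ni)
        t = stats.t.ppf(p, ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t ** 2) * ni)
        side = "low" if work[j] < m else "high"
        rows.append({"i": i, "value": work[j], "index": orig_indices[j],
                     "R": R, "lam": lam, "side": side,
                     "exceeds": bool(R > lam)})
        removed_idx.append(orig_indices[j])
        work = np.delete(work, j)
        orig_indices.pop(j)

    table = pd.DataFrame(rows)
    k = 0
    for r in rows:
        if r["exceeds"]:
            k = r["i"]
    out_rows = [r for r in rows[:k]
                if tail == "both" or r["side"] == tail]
    table["is_outlier"] = [r["i"] <= k and
                           (tail == "both" or r["side"] == tail)
                           for r in rows]
    return RosnerResult(n_outliers=len(out_rows),
                        outlier_indices=[r["index"] for r in out_rows],
                        table=table)


def heterozygosity_outliers(matrix: GenotypeMatrix, alpha: float = 0.05,
                            max_k: int = 10, tail: str = "both"
                            ) -> HeterozygosityReport:
    """Heterozygosity report with Rosner outlier flags attached.

    Inbred genotypes show up as low-H outliers relative to the cohort
    distribution, which is the screen used alongside pedigree-based
    inbreeding detection."""
    rep = heterozygosity(matrix)
    ok = ~np.isnan(rep.H)
    res = rosner_outliers(rep.H[ok], alpha=alpha, max_k=max_k, tail=tail)
    kept_ids = [ind for ind, m in zip(rep.individuals, ok) if m]
    rep.outliers = [kept_ids[i] for i in res.outlier_indices]
    rep.outlier_table = res.table
    return rep
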