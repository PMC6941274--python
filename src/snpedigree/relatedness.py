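"""Pairwise relatedness: IBS counting and method-of-moments IBD estimation.

The PI_HAT statistic (P(IBD=2) + P(IBD=1)/2, the expected proportion of
the genome shared identical by descent) is solved by the classical
moments approach: per-SNP probabilities of each identity-by-state class
conditional on the IBD state are accumulated from allele frequencies,
then the three IBD-state proportions are obtained by forward
substitution from the observed IBS counts and truncated into the
simplex.  First-degree relatives (parent-offspring, full sibs) have an
expectation of 0.5, half sibs 0.25, unrelated pairs 0.

PI_HAT is used here only as a loose prefilter (threshold 0.4) ahead of
Mendelian-error exclusion tests, so the estimator is intentionally the
plain moments version; a small-sample bias-corrected variant (unbiased
factorial-moment estimates of the allele-frequency powers) is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix


class InsufficientDataError(ValueError):
    """Too few overlapping non-missing SNPs for a stable estimate."""


@dataclass
class PairRelatedness:
    id1: str
    id2: str
    n_used: int
    ibs0: int
    ibs1: int
    ibs2: int
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float

    @property
    def pi_hat(self) -> float:
        return self.p_ibd2 + 0.5 * self.p_ibd1


def allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per SNP from diploid individuals only.

    SNPs with no non-missing diploid call get NaN and are excluded from
    all downstream moments computations.
    """
    dip = matrix.ploidy == 2
    g = matrix.calls[dip]
    nonmiss = (g >= 0)
    n_alleles = 2 * nonmiss.sum(axis=0)
    dose = np.where(nonmiss, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, dose / np.maximum(n_alleles, 1), np.nan)
    return freq


def _ibs_expectations(freqs: np.ndarray, counts: np.ndarray | None = None,
                      bias_correction: bool = False) -> np.ndarray:
    """Per-SNP P(IBS=s | IBD=z) terms needed by the moments solution.

    Returns an array of shape (5, n_snps) with rows
    e00 = P(IBS0|IBD0), e10 = P(IBS1|IBD0), e20 = P(IBS2|IBD0),
    e11 = P(IBS1|IBD1), e21 = P(IBS2|IBD1).

    With ``bias_correction`` the powers of p are replaced by their
    unbiased factorial-moment estimates from the observed allele counts
    (``counts`` = (alt_count, total_alleles) per SNP).
    """
    p = freqs
    q = 1 - p
    if not bias_correction:
        p2, p3, p4 = p ** 2, p ** 3, p ** 4
        q2, q3, q4 = q ** 2, q ** 3, q ** 4
        p2q2 = p2 * q2
        p3q1, p1q3 = p3 * q, p * q3
        p2q1, p1q2 = p2 * q, p * q2
    else:
        if counts is None:
            raise ValueError("bias correction needs allele counts")
        c, n = counts
        c = c.astype(float)
        n = n.astype(float)
        d = n - c

        def ff(x, k):  # falling factorial x(x-1)...(x-k+1)
            out = np.ones_like(x)
            for i in range(k):
                out = out * (x - i)
            return out

        def est(kp, kq):
            tot = ff(n, kp + kq)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(tot > 0, ff(c, kp) * ff(d, kq) / np.maximum(tot, 1), np.nan)

        p2, p3, p4 = est(2, 0), est(3, 0), est(4, 0)
        q2, q3, q4 = est(0, 2), est(0, 3), est(0, 4)
        p2q2 = est(2, 2)
        p3q1, p1q3 = est(3, 1), est(1, 3)
        p2q1, p1q2 = est(2, 1), est(1, 2)

    e00 = 2 * p2q2
    e10 = 4 * p3q1 + 4 * p1q3
    e20 = p4 + q4 + 4 * p2q2
    e11 = 2 * p2q1 + 2 * p1q2
    e21 = p3 + q3 + p2q1 + p1q2
    return np.vstack([e00, e10, e20, e11, e21])


def _solve_ibd(ibs0, ibs1, ibs2, E0, E1_0, E2_0, E1_1, E2_1, n_used):
    """Forward-substitute the IBD-state proportions from observed IBS
    counts and summed conditional expectations; truncate into [0,1] and
    renormalize."""
    z0 = ibs0 / E0 if E0 > 0 else 0.0
    z1 = (ibs1 - z0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
    z2 = (ibs2 - z0 * E2_0 - z1 * E2_1) / n_used if n_used > 0 else 0.0
    z = np.clip(np.array([z0, z1, z2]), 0.0, 1.0)
    s = z.sum()
    if s == 0:
        return 0.0, 0.0, 0.0
    z = z / s
    return float(z[0]), float(z[1]), float(z[2])


def _usable_snps(matrix: GenotypeMatrix, freqs: np.ndarray,
                 maf_min: float) -> np.ndarray:
    """SNPs informative for IBD moments: known frequency, MAF above the
    floor (monomorphic SNPs carry no IBS information and destabilize the
    solution)."""
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1 - freqs)
    return ~np.isnan(freqs) & (maf >= maf_min)


def estimate_pi_hat(matrix: GenotypeMatrix, i: str, j: str,
                    freqs: np.ndarray | None = None,
                    min_overlap: int = 1000, maf_min: float = 0.01,
                    bias_correction: bool = False) -> PairRelatedness:
    """Moments IBD estimate for one pair of diploid individuals."""
    ri, rj = matrix.row(i), matrix.row(j)
    if matrix.ploidy[ri] != 2 or matrix.ploidy[rj] != 2:
        raise ValueError("PI_HAT estimation is defined for diploid pairs")
    if freqs is None:
        freqs = allele_frequencies(matrix)
    gi, gj = matrix.calls[ri], matrix.calls[rj]
    use = (gi >= 0) & (gj >= 0) & _usable_snps(matrix, freqs, maf_min)
    n_used = int(use.sum())
    if n_used < min_overlap:
        raise InsufficientDataError(
            f"pair ({i},{j}): only {n_used} usable SNPs (< {min_overlap})")
    gi, gj = gi[use], gj[use]
    diff = np.abs(gi.astype(np.int16) - gj.astype(np.int16))
    ibs0 = int((diff == 2).sum())
    ibs2 = int((diff == 0).sum())
    ibs1 = n_used - ibs0 - ibs2

    counts = None
    if bias_correction:
        dip = matrix.ploidy == 2
        g = matrix.calls[dip][:, use]
        nm = g >= 0
        counts = (np.where(nm, g, 0).sum(axis=0), 2 * nm.sum(axis=0))
    E = _ibs_expectations(freqs[use], counts, bias_correction)
    sums = np.nansum(E, axis=1)
    p0, p1, p2 = _solve_ibd(ibs0, ibs1, ibs2, sums[0], sums[1], sums[2],
                            sums[3], sums[4], n_used)
    return PairRelatedness(i, j, n_used, ibs0, ibs1, ibs2, p0, p1, p2)


def pairwise_pi_hat(matrix: GenotypeMatrix, freqs: np.ndarray | None = None,
                    maf_min: float = 0.01, min_overlap: int = 1000
                    ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """PI_HAT for all diploid-diploid pairs, vectorized.

    Returns (diploid ids, pi_hat matrix, n_used matrix); entries with
    overlap below ``min_overlap`` are NaN.  IBS counts and per-pair
    expectation sums are assembled from indicator-matrix products, so the
    whole cohort is a handful of dense matmuls.
    """
    if freqs is None:
        freqs = allele_frequencies(matrix)
    ids = matrix.diploid_ids()
    rows = [matrix.row(i) for i in ids]
    usable = _usable_snps(matrix, freqs, maf_min)
    g = matrix.calls[rows][:, usable].astype(np.int16)
    E = _ibs_expectations(freqs[usable])
    m = (g >= 0)
    mf = m.astype(np.float64)

    A = [(m & (g == k)).astype(np.float64) for k in (0, 1, 2)]
    ibs2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    n_used = mf @ mf.T
    ibs1 = n_used - ibs0 - ibs2

    # per-pair sums of conditional IBS expectations over shared SNPs
    Esums = [mf @ (e * mf).T for e in E]  # symmetric since e per-SNP scalar
    E0, E1_0, E2_0, E1_1, E2_1 = Esums

    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = np.where(E0 > 0, ibs0 / np.maximum(E0, 1e-300), 0.0)
        z1 = np.where(E1_1 > 0,
                      (ibs1 - z0 * E1_0) / np.maximum(E1_1, 1e-300), 0.0)
        z2 = np.where(n_used > 0,
                      (ibs2 - z0 * E2_0 - z1 * E2_1) / np.maximum(n_used, 1),
                      0.0)
    Z = np.stack([z0, z1, z2]).clip(0.0, 1.0)
    s = Z.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(s > 0, Z / np.maximum(s, 1e-300), 0.0)
    pi = Z[2] + 0.5 * Z[1]
    pi[n_used < min_overlap] = np.nan
    np.fill_diagonal(n_used, 0)
    return ids, pi, n_used.astype(np.int64)


def candidate_pairs(matrix: GenotypeMatrix,
                    freqs: np.ndarray | None = None,
                    threshold: float = 0.4, maf_min: float = 0.01,
                    min_overlap: int = 1000) -> list[PairRelatedness]:
    """All unordered diploid-diploid pairs with PI_HAT strictly above the
    threshold (at threshold 0, every pair with a defined estimate —
    truncation can pin unrelated pairs at exactly 0)."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0,1]")
    if freqs is None:
        freqs = allele_frequencies(matrix)
    ids, pi, _ = pairwise_pi_hat(matrix, freqs, maf_min, min_overlap)
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if not np.isnan(pi[a, b]) and (pi[a, b] > threshold
                                           or threshold == 0):
                out.append(estimate_pi_hat(matrix, ids[a], ids[b], freqs,
                                           min_overlap, maf_min))
    return out


def write_pairs_tsv(pairs: list[PairRelatedness], path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tn_used\tibs0\tibs1\tibs2\tpi_hat\n")
        for p in pairs:
            fh.write(f"{p.id1}\t{p.id2}\t{p.n_used}\t{p.ibs0}\t{p.ibs1}\t"
                     f"{p.ibs2}\t{p.pi_hat:.4f}\n")
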