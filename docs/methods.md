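# Methods

`snpedigree` reconstructs multi-generation pedigrees in collections of
clonally propagated, mostly outbred germplasm (the motivating system is
apple, *Malus domestica*, where cultivars persist for centuries through
grafting) from dense biallelic SNP genotypes. The engine is a family of
exclusion tests: a hypothesized relationship is scored by counting the
SNPs whose genotype configuration is impossible under Mendelian
inheritance (Mendelian errors, ME), and accepted when that count falls
below a threshold placed in the gap between the error-driven counts of
true relationships and the far larger counts of all competing
relationships.

## Relationship tests

**Prefilter.** Testing every pair is unnecessary: first-degree pairs are
screened with the method-of-moments IBD estimator. For each pair, the
counts of SNPs sharing 0/1/2 alleles identical by state are combined
with per-SNP allele frequencies to solve the expected proportions of the
genome in IBD states 0/1/2 (forward substitution, truncation into the
simplex), giving PI_HAT = P(IBD=2) + P(IBD=1)/2. Parent-offspring and
full-sib pairs have expectation 0.5, half sibs 0.25, unrelated pairs 0.
Pairs with PI_HAT > 0.4 (deliberately loose — below 0.5 by more than the
estimator's spread) enter the exclusion tests. Monomorphic and
near-monomorphic SNPs (MAF < 0.01) are excluded from the moments
solution; they carry no IBS information. A bias-corrected variant
(unbiased factorial-moment estimates of the allele-frequency powers) is
available behind a flag; the prefilter is robust to the choice.

**Duo test.** For a putative parent-offspring pair, a SNP where one
individual is homozygous reference and the other homozygous alternate
(opposing homozygotes) is an ME. A per-chromosome breakdown is kept
because a *null allele* — e.g. a diverged, introgressed chromosomal
fragment where one allele fails to call — produces ME clustered on one
or two chromosomes; the diagnostic flags duos where more than half the
ME sit on at most two chromosomes.

**Two passes and the SNP blacklist.** Duos are first accepted at a
liberal rate on the full panel; SNPs showing an opposing-homozygote
error in two or more accepted duos are then removed (recurrent per-SNP
errors indict the marker, not the relationships), and duo ME are
recounted on the retained panel at the final rate.

**Trio test.** For an individual in two or more accepted duos, every
pair of its partners is tested as a parent couple. A SNP is an ME iff
the offspring opposes either parent homozygously, or the offspring is
heterozygous while both parents are homozygous for the same allele. Each
SNP contributes at most one ME, and a missing call in any tested role
skips the SNP (no imputation); the informative count is reported so
rates stay comparable. This per-SNP rule is exactly the complement of
"some gamete pair of the two parents can produce the offspring" — the
test suite asserts the equivalence against a brute-force gamete
enumeration over all 27 genotype configurations.

**Grandparent test.** For a duo with no second parent found, the parent
couple of the missing parent is sought: a SNP is an ME iff both
candidate grandparents are homozygous for the same allele while the
offspring is homozygous for the alternate allele, or heterozygous with
the accepted parent homozygous for the grandparents' allele (the missing
parent would have had to transmit an allele the grandparent couple
cannot supply). The search is two-stage for tractability: a liberal
screen on a random 10% subpanel, then a strict recount on the full
panel. Both role assignments of an unoriented duo are tested. By default
grandparent candidates are restricted to individuals with PI_HAT ≥ 0.15
to the offspring (grandparents have expectation 0.25); an exhaustive
flag lifts the restriction for small cohorts.

**Triploids.** Triploids (2n gamete from one parent + n gamete from the
other) are recoded pseudo-diploid (dosage 0 → hom ref, 1 and 2 → het,
3 → hom alt) and screened with the duo test against all diploids. The
two parents are separated by the tri-hom/di-het count — SNPs homozygous
in the recoded triploid but heterozygous in the candidate: near zero for
the 2n-gamete parent (both alleles are transmitted, barring FDR/SDR
crossover reassortment, available in the simulator as a per-SNP rate),
large for the n-gamete parent. A candidate is labelled the n-gamete
parent only when the triploid trio is accepted; other low-ME/high-count
candidates remain sibs-or-unresolved. Finally, diploids that look like
offspring of the triploid are challenged with a transmission test: at
SNPs where the triploid is heterozygous and its 2n parent homozygous,
the third allele came through the n gamete; a true offspring of the
triploid is homozygous for that allele at a substantial fraction of
informative SNPs (≈ q/3 of them), while an offspring of the 2n parent
essentially never is. The count_ii ceiling defaults to
max(25, 1e-4 × panel) — there is no principled external value for it, so
it is set well above the error-driven expectation (≈ ε/2 per informative
SNP) and far below the true-offspring signal.

## Thresholds

All thresholds are configured as per-SNP rates and realized as
round(rate × panel size), floored at 1 so error-free relationships
(exactly 0 ME) always pass; acceptance is strict less-than. The default
`ThresholdConfig` encodes the rates used on the reference germplasm
panel (duo 600/253,095 ≈ 0.24%; liberal first pass 1000/275,223; trio
600/253,095; grandparent stages 100/25,310 and 100/253,095; triploid duo
and trio 300/253,095; tri-hom/di-het 1200/253,095). Those rates are tied
to that panel's error process.

Thresholds in this method are data-dependent by construction — they are
placed in the empirical gap of the ME distribution. For a dataset with a
known per-call error rate ε, `ThresholdConfig.for_error_rate(ε)` makes
that placement analytically: under uniform misclassification, a single
miscall creates opposing homozygotes in a true duo at ≈ 0.65 ε per SNP
(both-homozygous-same configurations contribute ε, homozygote ×
heterozygote ones ε/2) and violates a true trio at ≈ 1.5 ε, while the
nearest competing relationship (full sibs for duos) errs at
≈ 0.5 E[(2pq)²]/4 ≈ 0.017 per SNP under a U(0.05, 0.5) MAF spectrum —
an order of magnitude higher. The chosen multiples (duo 3ε, first pass
5ε, trio 4.5ε, grandparent stages 4ε/3ε, triploid 3ε/4.5ε, tri-hom/
di-het 4ε) sit several Poisson standard deviations above the
error-driven mean and about 3× below the full-sib floor at panel sizes
of a few thousand SNPs. Gap detection itself is offered only as a report
(largest empty interval of the ME distribution), never as an automatic
threshold.

## Orientation and pedigree assembly

Accepted duos are symmetric; roles are assigned by precedence:

1. trio membership — a trio offspring must be the parent in its other
   duos (it cannot have a third parent), and each newly inferred
   offspring propagates the same argument iteratively to a fixed point;
2. documented parentage from passport metadata;
3. documented dates — later-dated member is the offspring, only when
   both dates are present, flagged precise, and at least `min_year_gap`
   (default 10) years apart; the sources of historical dates are too
   noisy for closer calls, and the gap is configurable and logged;
4. propagation re-runs; an accepted grandparent group also fixes its
   duo's roles (the member with the inferred grandparent couple is the
   offspring).

Parentage outranks dates when they disagree (the disagreement is
recorded). Contradictions — an individual forced into both roles, a
directed cycle, or two date-oriented duos whose joint parents fail the
trio test — are recorded as conflicts and/or marked suspect, never
silently resolved.

Trios contribute two parent edges, oriented duos one; each grandparent
group adds a placeholder node (the ungenotyped missing parent) with the
couple as its parents and the orphan offspring as its only child.
Unoriented duos stay out of the pedigree. Node classes follow the
germplasm-pedigree convention: 1 founder, 2 placeholder with both
parents known, 3 semi-founder, 4 both parents known. Generation depth is
1 for founders and 1 + max over parents otherwise; placeholders count in
depth (they sit between the grandparent couple and the offspring).
Descendant counts follow descent *through* placeholders but do not count
them — only named genotypes. A node is inbred iff the inclusive ancestor
sets of its two parents intersect; "inclusive" makes a recurrent parent
(also a grandparent of the same node) register as inbreeding.
Graph plumbing (components, ancestor/descendant closures, cycle checks,
topological order) delegates to networkx.

Per-individual heterozygosity (fraction of heterozygous calls among
non-missing) complements pedigree-based inbreeding: inbred genotypes
fall in the low tail, screened with the generalized extreme studentized
deviate (Rosner) test (two-sided statistics; reporting can be restricted
to one tail). The test requires n of a few dozen and positive variance,
and raises otherwise.

## The synthetic cohorts

The simulator gene-drops founder genotypes (Hardy–Weinberg, MAF
~ U(0.05, 0.5) by default) through a random multi-generation pedigree:
each non-founder draws two distinct parents from earlier generations,
with preferential attachment (weight 1 + α · current offspring count,
α = 1) producing the hub parents typical of germplasm; parent×child and
other consanguineous crosses are allowed, as in real collections. Loci
are unlinked — linkage is irrelevant to per-SNP exclusion counts — but
carry chromosome labels (17 chromosomes) so clustered diagnostics are
testable. On top of clean transmission it plants: uniform per-call
misclassification (default ε = 0.002), missingness (0.005), an optional
null-allele segment (heterozygous calls of affected individuals become
homozygous-reference within a chromosome span), triploids (2n gamete =
faithful parental copy, optional per-SNP reassortment rate r, default 0,
matching the near-zero tri-hom/di-het counts of real 2n gametes), and
passport metadata in which dates are missing (0.2), wrong (0.1, planted
older than the founder era so chronology checks can catch them) or
approximate (0.1), and parentage is documented (0.3) or wrongly
documented (0.05). Everything derives from one mandatory seed;
`mask_individuals` removes genotypes while the truth pedigree keeps
them, creating the missing-parent scenario for the grandparent search.

What the simulator does *not* emulate: linkage disequilibrium and
coalescent founder haplotypes, selection or assortative mating, the
SNP-specific error structure of real intensity-based array genotyping,
and genotype duplicates or synonym curation. Passing tests therefore demonstrate the logic and
calibration of the exclusion machinery under a faithful error model, not
array-specific behaviour on real intensity data.

## Reference study conditions

The validation cohort is 60 founders + 3 × 47 offspring over four
generations (201 individuals; variants add 3 triploids and a null-allele
segment on chromosome 13), 5000 SNPs, ε = 0.002, missingness 0.005 —
sized so the whole suite runs in seconds on one CPU while every stage
(prefilter, two-pass duos, blacklist, trios, grandparents, triploids,
orientation, pedigree) keeps dozens to hundreds of true relationships to
score. Under these conditions the pipeline recovers 100% of true trios
with zero false duos or trios, recovers masked parents' parent couples,
assigns triploid gamete parents correctly, and orients duos with 100%
accuracy on clean metadata (measured quantities, recomputed by
`scripts/acceptance.py` and the test suite).

## Numerical and degenerate-input choices

* Missing calls are a distinct sentinel (-1); any missing call among the
  tested roles skips the SNP in every test.
* Random SNP subpanels use floor(fraction × n) — deterministic and
  documented; order within the panel is preserved.
* IBD proportions are truncated to [0,1] and renormalized; pairs below a
  minimum usable overlap (default 1000 SNPs) raise an
  insufficient-data error rather than returning an unstable estimate.
* The pseudo-diploid recoding treats a track containing a dosage of 3 as
  raw and anything else as already recoded (raw 2 = ABB het and recoded
  2 = hom alt collide numerically); the matrix constructor always forces
  raw semantics.
* Pedigree construction refuses a third distinct parent and any directed
  cycle, naming the offending nodes.
* The Rosner test declares the largest i with R_i > λ_i outliers, with
  t-distribution critical values; it raises on zero variance and on
  n ≤ max_k + 2.

## Known limitations

* The duo test cannot separate parent-offspring from full sibs when
  panels are small and error rates high; the trio stage and thresholds
  carry that burden (full sibs sit ~3× above the duo threshold under the
  reference conditions, ~10× in ME rate).
* Grandparent candidates restricted by PI_HAT ≥ 0.15 can miss couples
  when the offspring's genotype quality is poor; the exhaustive flag
  trades time for completeness.
* Orientation by dates inherits the error rate of the documented dates;
  wrong documented parentage propagates (it outranks dates by design).
* Maternal vs paternal roles are not identifiable from genotypes alone,
  and likelihood-based parentage (LOD scores) or haplotype-sharing
  approaches are out of scope.
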