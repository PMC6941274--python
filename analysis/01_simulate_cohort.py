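#!/usr/bin/env python
"""Generate the synthetic study cohort and write it in the exchange
formats the rest of the analysis reads back (matrix TSV + map, metadata
CSV, truth JSON)."""

from _common import COHORT, DATA

import snpedigree as sp
from snpedigree.genotype_io import write_map, write_matrix, write_metadata

DATA.mkdir(parents=True, exist_ok=True)
matrix, meta, truth = sp.simulate(COHORT)

write_matrix(matrix, DATA / "genotypes.tsv")
write_map(matrix.panel, DATA / "genotypes.map")
write_metadata(meta, DATA / "metadata.csv")
truth.to_json(DATA / "truth.json")

n_gen = max(truth.generation.values())
print(f"cohort: {matrix.n_individuals} individuals "
      f"({len(matrix.triploid_ids())} triploid) x {matrix.n_snps} SNPs, "
      f"{n_gen} generations")
print(f"true parent-offspring links: {2 * len(truth.pedigree)}; "
      f"perturbed calls: {truth.n_error_calls}; "
      f"null-allele segment: {len(truth.null_allele_snps)} SNPs on chr13 "
      f"affecting {truth.null_allele_affected}")
print(f"metadata corruption: {len(truth.missing_date_ids)} missing dates, "
      f"{len(truth.wrong_date_ids)} wrong dates, "
      f"{len(truth.wrong_parentage_ids)} wrong documented parentages")
print(f"wrote {DATA}")
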