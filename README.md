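# snpedigree

Pedigree reconstruction in clonal germplasm collections from dense
biallelic SNP genotypes, by Mendelian-error exclusion testing.

Collections of grafted crops (the motivating case is apple, *Malus
domestica*) preserve cultivars for centuries, so the parents and
grandparents of a cultivar are often still alive in some orchard. With
enough SNPs, relationships can be inferred by pure exclusion: a
hypothesized relationship is scored by counting genotype configurations
impossible under Mendelian inheritance — Mendelian errors (ME) — and
accepted when the count falls below a threshold placed in the gap
between the near-zero counts of true relationships and the much larger
counts of everything else.

The package implements the full analysis as a library plus numbered
analysis scripts:

* **prefilter** — method-of-moments IBD (PI_HAT = P(IBD=2) + ½P(IBD=1))
  over all diploid pairs; pairs above 0.4 are candidate first-degree
  relatives;
* **duos** — opposing-homozygote ME for parent-offspring pairs, in two
  passes around a blacklist of recurrently erring SNPs (null alleles),
  with per-chromosome clustering diagnostics;
* **trios** — for each individual in ≥ 2 duos, every pair of partners is
  tested as a parent couple (opposing homozygotes, plus heterozygous
  offspring with both parents homozygous for the same allele);
* **grandparents** — for duos with a missing second parent, a two-stage
  search (random 10% subpanel, then full panel) for the parent couple of
  the missing parent;
* **triploids** — pseudo-diploid recoding, 2n-gamete parent
  identification via tri-hom/di-het counts, triploid trios, and a
  transmission test that excludes a triploid as the parent of diploids
  that are really offspring of its 2n-gamete parent;
* **orientation** — parent/offspring roles from trio membership,
  documented parentage, documented dates, propagated to a fixed point
  with explicit conflict reporting;
* **pedigree** — assembly into a DAG with placeholder nodes for missing
  parents; generations, founders, descendants, inbreeding, network
  components, chronology checks;
* **synthetic data** — a gene-dropping simulator (founders in HWE,
  multi-generation Mendelian transmission, genotyping error,
  missingness, null-allele segments, triploids, corrupted passport
  metadata) with a full truth set, so every stage is validated without
  any external download.

See `docs/methods.md` for the model, the threshold calibration and the
design decisions.

## Worked example

```python
import snpedigree as sp

cfg = sp.SimulationConfig(n_founders=60, n_generations=4,
                          offspring_per_generation=47, n_snps=5000,
                          error_rate=0.002, missing_rate=0.005, seed=7)
matrix, metadata, truth = sp.simulate(cfg)

thr = sp.ThresholdConfig.for_error_rate(0.002)
run = sp.run_all(matrix, metadata, sp.PipelineConfig(thresholds=thr, seed=7))
for line in run.log:
    print(line)
```

prints

```
prefilter: 302 pairs with PI_HAT > 0.4
duo pass 1: 282 accepted below 50 ME on 5000 SNPs
blacklist: removed 450 SNPs, 4550 retained
duo pass 2: 282 accepted below 27 ME on 4550 SNPs
trios: 141 of 1288 candidates accepted below 41 ME
grandparents: 0 groups accepted (stage thresholds 4, 27)
pedigree: 187 nodes, 46 founders, 4 generations
```

Reading: 302 pairs passed the relatedness prefilter; 282 survived the
duo exclusion test (the thresholds are the per-SNP rates realized on the
current panel — 50, then 27 ME after 450 recurrently erring SNPs were
blacklisted); 141 complete parent-offspring trios were accepted out of
1288 tested combinations. Checked against the simulator's truth set,
those are exactly the 282 true parent-offspring pairs and all 141 true
trios, with zero false positives; every duo was absorbed into a trio
(both parents genotyped), so no grandparent search or orientation was
needed in this clean scenario. Masking a genotyped parent
(`sp.mask_individuals`) makes its children's duos orphans, and the
grandparent stage then recovers the masked parent's parent couple — see
`analysis/04_trios_and_grandparents.py`.

The numbered scripts under `analysis/` run the same machinery as a
narrative on a richer cohort (triploids, a null-allele segment on
chromosome 13, corrupted metadata) and write tables under
`results/analysis/`:

```bash
cd analysis
python 01_simulate_cohort.py     # writes results/data/ (matrix TSV, map, metadata CSV, truth JSON)
python 02_relatedness_prefilter.py
python 03_duo_exclusion.py       # flags the planted null-allele duos on chr13
python 04_trios_and_grandparents.py
python 05_triploid_parentage.py  # 2n/n-gamete parents, exclusion verdicts
python 06_orientation_and_pedigree.py
```

A thin CLI wraps the same pipeline for file-based use:
`snpedigree simulate --seed 7 --out-dir sim && snpedigree run-all
--matrix sim/genotypes.tsv --map sim/genotypes.map --metadata
sim/metadata.csv --out-dir out`.

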