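"""Shared paths and cohort configuration for the analysis scripts."""

from pathlib import Path

import snpedigree as sp

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results" / "analysis"

SEED = 2024
ERROR_RATE = 0.002
MISSING_RATE = 0.005

#: the study cohort: 60 founders + 3 x 47 offspring + 3 triploids over
#: four generations, 5000 unlinked SNPs on 17 chromosomes, per-call error
#: 0.002, missingness 0.005, a null-allele segment on chromosome 13, and
#: passport metadata with 20% missing and 10% wrong dates.
COHORT = sp.SimulationConfig(
    n_founders=60, n_generations=4, offspring_per_generation=47,
    n_snps=5000, error_rate=ERROR_RATE, missing_rate=MISSING_RATE,
    n_triploids=3,
    null_allele=sp.NullAlleleSpec(chromosome=13, start_fraction=0.2,
                                  end_fraction=0.8, n_affected=3),
    seed=SEED,
)

THRESHOLDS = sp.ThresholdConfig.for_error_rate(ERROR_RATE)


def load_cohort():
    matrix = sp.read_matrix(DATA / "genotypes.tsv",
                            map_path=DATA / "genotypes.map")
    meta = sp.read_metadata(DATA / "metadata.csv")
    truth = sp.TruthSet.from_json(DATA / "truth.json")
    return matrix, meta, truth
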